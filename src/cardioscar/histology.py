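"""Semi-quantitative histology scoring of heterogeneous scar tissue.

Sections of the scar border zone are scored on a five-level ordinal scale
(+ ... +++++) for fibrosis extension, connexin-43 quantity, connexin-43
polarity, cardiomyocyte viability, and vascularization, separately for the
endocardial and epicardial halves of the wall.  Levels map linearly to
percentages (20/40/60/80/100 %), and per-animal values are the section-area
weighted means of those percentages, so larger regions of heterogeneous
tissue contribute proportionally more.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HISTO_VARIABLES",
    "GRID_SQUARE_MM2",
    "ordinal_to_percent",
    "weighted_animal_mean",
    "animal_summary",
]

HISTO_VARIABLES = (
    "fibrosis",
    "cx43_quantity",
    "cx43_polarity",
    "viability",
    "vascularization",
)

#: area of one square of the 20 mm x 40 mm / 1250-square counting grid
GRID_SQUARE_MM2 = (20.0 * 40.0) / 1250.0


def ordinal_to_percent(level):
    """Convert ordinal scores (1..5, i.e. + .. +++++) to percentages.

    Level k maps to 20*k percent. Accepts scalars or arrays.
    """
    arr = np.asarray(level)
    if not np.issubdtype(arr.dtype, np.integer):
        as_int = np.asarray(level, dtype=float)
        if not np.all(as_int == np.rint(as_int)):
            raise ValueError("ordinal levels must be integers in 1..5")
        arr = np.rint(as_int).astype(int)
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError("ordinal levels must be in 1..5")
    out = 20.0 * arr
    return float(out) if np.isscalar(level) else out


def weighted_animal_mean(extents_mm2, levels) -> float:
    """Area-weighted mean percentage of one variable over an animal's sections.

    Parameters
    ----------
    extents_mm2 : array-like
        Heterogeneous-tissue extent of each section.  May also be given in
        grid squares; only the relative weights matter.
    levels : array-like
        Ordinal level (1..5) per section.

    Returns
    -------
    float
        ``sum(extent_i * percent_i) / sum(extent_i)`` in percent.
    """
    w = np.asarray(extents_mm2, dtype=float).ravel()
    p = np.atleast_1d(ordinal_to_percent(levels)).astype(float)
    if w.size == 0 or w.size != p.size:
        raise ValueError("extents and levels must be nonempty and equal length")
    if np.any(w <= 0):
        raise ValueError("section extents must be > 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("total section extent must be > 0")
    return float(np.sum(w * p) / total)


def animal_summary(sections: pd.DataFrame) -> pd.DataFrame:
    """Per-animal, per-compartment weighted means of every scored variable.

    Parameters
    ----------
    sections : DataFrame
        Long-format table with columns ``animal_id, section_id, compartment,
        ht_extent_mm2, variable, ordinal_level`` (one row per section and
        variable), as written by the synthetic generator.

    Returns
    -------
    DataFrame
        Columns ``animal_id, compartment, variable, weighted_mean_percent``.
    """
    required = {
        "animal_id",
        "section_id",
        "compartment",
        "ht_extent_mm2",
        "variable",
        "ordinal_level",
    }
    missing = required - set(sections.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    rows = []
    for (animal, comp, var), grp in sections.groupby(
        ["animal_id", "compartment", "variable"], sort=True
    ):
        rows.append(
            {
                "animal_id": animal,
                "compartment": comp,
                "variable": var,
                "weighted_mean_percent": weighted_animal_mean(
                    grp["ht_extent_mm2"].to_numpy(),
                    grp["ordinal_level"].to_numpy(),
                ),
            }
        )
    return pd.DataFrame(rows)
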