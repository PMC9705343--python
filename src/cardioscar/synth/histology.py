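"""Synthetic semi-quantitative histology score tables.

Each animal contributes several sections per compartment (endocardial /
epicardial half of the wall); every section carries a heterogeneous-tissue
extent and a five-level ordinal score per variable drawn from configurable
categorical distributions.  The generated table matches the long CSV layout
consumed by the histology module, and the result carries the per-animal
area-weighted means as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..histology import HISTO_VARIABLES, animal_summary

__all__ = ["SyntheticHistoSpec", "SyntheticHistoResult", "generate_histology"]

COMPARTMENTS = ("endo", "epi")

#: default ordinal distributions (probability of levels 1..5), loosely
#: mid-scale for every variable
_UNIFORMISH = (0.1, 0.2, 0.4, 0.2, 0.1)


def _default_level_probs():
    return {
        comp: {var: _UNIFORMISH for var in HISTO_VARIABLES} for comp in COMPARTMENTS
    }


@dataclass
class SyntheticHistoSpec:
    """Parameters of one cohort's histology tables."""

    animal_ids: tuple = ("A1",)
    n_sections: int = 6
    #: uniform range of section HT extent, mm^2
    extent_range_mm2: tuple[float, float] = (15.0, 80.0)
    #: ``{compartment: {variable: 5 probabilities for levels 1..5}}``
    level_probs: dict = field(default_factory=_default_level_probs)
    seed: int = 0

    def validate(self):
        if self.n_sections < 1:
            raise ValueError("need at least one section per animal")
        if len(self.animal_ids) == 0:
            raise ValueError("need at least one animal")
        lo, hi = self.extent_range_mm2
        if not (0 < lo <= hi):
            raise ValueError("section extents must be > 0")
        for comp in COMPARTMENTS:
            for var in HISTO_VARIABLES:
                p = np.asarray(self.level_probs[comp][var], dtype=float)
                if p.shape != (5,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                    raise ValueError(
                        f"{comp}/{var}: level probabilities must be 5 nonnegative "
                        "values summing to 1"
                    )


@dataclass
class SyntheticHistoResult:
    sections: pd.DataFrame
    gt_animal_means: pd.DataFrame


def generate_histology(spec: SyntheticHistoSpec) -> SyntheticHistoResult:
    """Draw one cohort's section table; deterministic for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for animal in spec.animal_ids:
        for comp in COMPARTMENTS:
            extents = rng.uniform(*spec.extent_range_mm2, size=spec.n_sections)
            for sec in range(spec.n_sections):
                for var in HISTO_VARIABLES:
                    level = int(
                        rng.choice(
                            np.arange(1, 6), p=np.asarray(spec.level_probs[comp][var])
                        )
                    )
                    rows.append(
                        {
                            "animal_id": animal,
                            "section_id": f"{comp}-{sec:02d}",
                            "compartment": comp,
                            "ht_extent_mm2": float(extents[sec]),
                            "variable": var,
                            "ordinal_level": level,
                        }
                    )
    sections = pd.DataFrame(rows)
    return SyntheticHistoResult(
        sections=sections, gt_animal_means=animal_summary(sections)
    )
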