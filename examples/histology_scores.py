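"""Semi-quantitative histology: ordinal scores to area-weighted means.

Five-level scores (+ ... +++++) become 20..100 %, then each animal's value
is the mean over its sections weighted by the heterogeneous-tissue extent
of each section.
"""

from cardioscar.histology import animal_summary, ordinal_to_percent
from cardioscar.synth.histology import SyntheticHistoSpec, generate_histology

print("ordinal scale:", {k: ordinal_to_percent(k) for k in range(1, 6)})

res = generate_histology(
    SyntheticHistoSpec(animal_ids=("P01", "P02"), n_sections=6, seed=3)
)
summary = animal_summary(res.sections)
epi = summary[summary.compartment == "epi"]
print("\nepicardial per-animal weighted means (%):")
print(
    epi.pivot(index="animal_id", columns="variable", values="weighted_mean_percent")
    .round(1)
    .to_string()
)
print("\nEach value is sum(extent_i * percent_i) / sum(extent_i) over that")
print("animal's sections: larger heterogeneous-tissue regions weigh more.")
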