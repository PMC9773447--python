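"""Recombinant production capacity by disulfide folding difficulty.

Scans how much extra disulfide-bonded protein a condition can absorb before
host substrates accumulate beyond 0.5%, for recombinant proteins of
increasing folding difficulty.
"""

from dsbfold import SyntheticSpec, capacity_scan, ground_truth_condition
from dsbfold.capacity import ConditionModel

cond = ground_truth_condition(SyntheticSpec(seed=1))
condition = ConditionModel(
    cond.label, cond.truth, cond.pools, cond.mu, cond.proteome.total_copies
)

print(f"condition {condition.label}: mu = {condition.mu}/h")
print("recombinant capacity (percent of total cellular protein synthesis):")
for cat in ("cat1", "cat2", "cat3"):
    res = capacity_scan(condition, cat)
    print(f"  {cat}: {res.max_synthesis_fraction:6.2f}%")
# Capacity falls sharply with folding difficulty: a protein needing heavy
# isomerase support (cat3) can be produced at only a fraction of the rate of
# an easy two-cysteine substrate (cat1), because the DsbC/DsbG/DsbD branch is
# provisioned far below the DsbA/DsbB oxidation branch.
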