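#!/usr/bin/env python
"""Operating characteristics of the interval-separation classifier on
synthetic regions with known family-level utilization biases.

Two experiments on an East Sepik-scale synthetic flora (~85 families,
~2,000 taxa, 9% baseline use probability):

1. null calibration - all families neutral; the per-family false-positive
   rate of the 95% interval-separation rule;
2. power - one family pinned to 120 taxa with an 8x boost over a 5%
   baseline; the fraction of seeded replicates in which it is recovered
   as overused.

Findings (seed 1, 300/200 replicates): the null false-positive rate sits
a little under 5% (small families with a single reported taxon are the
dominant false positives, exactly as in the published tables), and the
planted 8x family is recovered in >=95% of replicates.
"""
import json
from pathlib import Path

import ethnoutil as eu

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

null_cfg = eu.SimConfig(seed=eu.derived_seed(SEED, 1))
null = eu.recovery_experiment(null_cfg, 300)
fpr = 1.0 - null["specificity"]
t = null["table"]
print(f"null per-family false-positive rate (300 reps): {fpr:.4f}")

planted_cfg = eu.SimConfig(seed=eu.derived_seed(SEED, 2),
                           baseline_use_prob=0.05, effects={0: 8.0},
                           fixed_sizes={0: 120})
power = eu.recovery_experiment(planted_cfg, 200)
pt = power["table"]
rate = pt[pt.family == "Simfam000aceae"].correct.mean()
print(f"planted 8x family (120 taxa) recovered in {rate:.1%} of 200 reps")

null["table"].to_csv(OUT / "05_null_classifications.tsv", sep="\t",
                     index=False)
pt.to_csv(OUT / "05_power_classifications.tsv", sep="\t", index=False)
(OUT / "05_recovery_summary.json").write_text(json.dumps({
    "null_false_positive_rate": fpr,
    "null_reps": 300,
    "planted_detection_rate": float(rate),
    "planted_reps": 200,
    "seed": SEED,
}, indent=2, sort_keys=True) + "\n")
print(f"wrote {OUT / '05_recovery_summary.json'}")
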