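"""The synthetic-cohort generator and parameter recovery.

The default configuration mirrors the field study: 4 populations x 2
morphs x 2 pollination treatments, ~80-100 plants per cell, published
trait means/SDs and fitness levels, and a gradient scenario encoding
the study's qualitative findings. At large n the estimation pipeline
recovers the configured parameters — the generator is the ground truth
against which the analysis is validated.
"""

import numpy as np

import pollsel as ps

cfg = ps.default_config(n=2000)
table = ps.simulate_cohort(cfg, seed=7)
truth = ps.truth_table(cfg)

grads = ps.estimate_gradients(table)
merged = grads.merge(
    truth, on=["population", "morph", "treatment", "trait"], suffixes=("_hat", "_true")
)
err = np.abs(merged["beta_hat"] - merged["beta_true"])
within = (err <= 3 * merged["se"]).mean()
print(f"cohort: {len(table)} plants in {len(table.group_keys())} cells (n=2000 each)")
print(f"gradient recovery: max |beta_hat − beta_true| = {err.max():.4f}")
print(f"  {100*within:.1f}% of 80 (cell, trait) estimates within 3 SE of truth")

pl_hat = ps.report_frame(ps.pollen_limitation_report(table, n_boot=200, seed=7))
pl_true = truth[truth.treatment == "C"].groupby(["population", "morph"])["pl"].first()
pl_err = [
    abs(r.pl - pl_true.loc[(r.population, r.morph)]) for r in pl_hat.itertuples()
]
print(f"pollen-limitation recovery: max |PL_hat − PL_true| = {max(pl_err):.4f}")
print(
    "\nBoth the gradient scenario and the configured pollen limitation are\n"
    "recovered to sampling precision, so pipeline results on field-scale\n"
    "cohorts can be benchmarked against known truth."
)
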