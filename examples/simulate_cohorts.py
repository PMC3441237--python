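"""Generate synthetic multi-cohort expression data with a known module.

Each cohort carries a latent per-patient target activity that drives a
designated target probe, a signed co-expression module around it, and a
logistic pCR/RD outcome. Files land in ./scratch_example_cohorts/ with a
ground-truth JSON sidecar per cohort.
"""

from targetindex.pipeline import run_simulate

cfg = run_simulate(
    "scratch_example_cohorts",
    n_cohorts=3, n_samples=200, n_genes=2000, n_pos=50, n_neg=25, seed=1,
)

print(f"wrote {cfg.n_cohorts} cohorts ({cfg.n_samples} patients x {cfg.n_genes} probes each)")
print(f"target probe drives a {cfg.n_pos}/{cfg.n_neg} signed module;")
print(f"pCR prevalence ~{1/(1+pow(2.718281828, -cfg.outcome_intercept)):.0%} when the effect is weak")
# The *_truth.json sidecars list the true module probes and the latent
# activity, so downstream discovery can be scored against the truth.
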