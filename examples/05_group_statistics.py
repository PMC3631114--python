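"""Paired t-test, two-way ANOVA and Tukey-Kramer post-hoc comparisons.

Simulates the study's statistical layer: per-sample first/last moduli
for the paired fatigue test, and a 2x2 (histology x treatment) pore-area
dataset with unbalanced cells for ANOVA + post-hoc.
"""

import numpy as np

import bonepore as bp

rng = np.random.default_rng(7)

# paired t: 12 samples, modulus drops ~5.7% from first to last cycle
m_first = rng.normal(142.0, 19.0, 12)
m_last = m_first * rng.normal(0.943, 0.02, 12)
t_res = bp.paired_t_test(m_first, m_last)
print(f"paired t-test: t = {t_res.t:.2f}, df = {t_res.df}, p = {t_res.p:.4f}")

# two-way ANOVA on pore area: histology and treatment both raise the mean
vals, fa, fb = [], [], []
for n, mean, a, b in [(12, 300.0, "AM", "F"), (12, 250.0, "AM", "C"),
                      (16, 420.0, "PL", "F"), (16, 350.0, "PL", "C")]:
    vals.extend(rng.normal(mean, 60.0, n))
    fa.extend([a] * n)
    fb.extend([b] * n)
ds = bp.TwoFactorDataset(np.array(vals), np.array(fa), np.array(fb))

table = bp.two_way_anova(ds, ss_type=3).table
print("\ntwo-way ANOVA (Type III):")
print(table[["sum_sq", "df", "F", "p"]].round(4).to_string())

tukey = bp.tukey_posthoc(ds)
print("\nTukey-Kramer post-hoc (stars: p < 0.05/0.02/0.01):")
print(tukey.comparisons[["group1", "group2", "mean_diff", "p_adj", "stars"]]
      .round(4).to_string(index=False))
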