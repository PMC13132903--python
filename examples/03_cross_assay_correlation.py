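"""Genotype-level aggregation and the cross-assay correlation matrix.

Simulates a 105-line panel in which two traits share a latent correlation of
0.8 while the third is independent, then recovers line means with bootstrap
CIs and the pairwise regression matrix, including the attenuation that
replicate noise imposes on the observed between-line slope.
"""

import numpy as np

import socialfly as sf

R = np.array([[1.0, 0.8, 0.0],
              [0.8, 1.0, 0.0],
              [0.0, 0.0, 1.0]])
spec = sf.LinePanelSpec(
    seed=3, corr=R,
    trait_means=(0.0, 0.0, 0.0), line_sds=(1.0, 1.0, 1.0),
    resid_sds=(1.0, 1.0, 1.0), reps_per_line=20,
)
panel, latents = sf.simulate_line_panel(spec)

means = sf.line_means(panel, "preference", n_boot=2000, seed=1)
print("first three line means with 95% bootstrap CIs (trait 'preference'):")
print(means.head(3).to_string(index=False))

matrix = sf.cross_assay_matrix(panel, ["preference", "latency", "interactions"])
print("\npairwise regressions on z-scored line means "
      "(slope = Pearson r, R^2 = slope^2):")
print(matrix[["trait_x", "trait_y", "slope", "slope_se", "r_squared",
              "p_value", "p_bh", "n_lines"]].to_string(index=False))

lam = 1.0 / (1.0 + 1.0 / spec.reps_per_line)  # reliability of a 20-rep line mean
print(f"\nlatent correlation 0.8 x attenuation {lam:.3f} = {0.8 * lam:.3f}: "
      "the preference-latency slope sits near this value, the independent "
      "pairs near zero.")
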