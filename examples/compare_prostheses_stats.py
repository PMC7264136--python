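"""Compare MAR efficacy across prosthesis-like groups with Welch statistics.

Simulates four groups of phantom pairs that differ only in how many
streaks MAR removes (the 'gold' group gets the strongest reduction), then
runs the heteroscedasticity-robust layer: Shapiro-Wilk normality, Welch's
one-way ANOVA and the Games-Howell post hoc test on the reduction ratios.
"""

import numpy as np

from marquant import (
    GroupSample,
    analyze_pair,
    games_howell,
    make_pair,
    shapiro_wilk,
    welch_anova,
)

rng = np.random.default_rng(2)
groups = []
for label, k_on in [("amalgam", 6), ("gold", 2), ("pfm", 6), ("zirconia", 7)]:
    ratios = []
    for _ in range(6):
        sim = make_pair(k_off=10, k_on=k_on, noise_sigma=5.0,
                        seed=int(rng.integers(0, 2**31)))
        ratios.append(analyze_pair(sim.pair).reduction_ratio_pct)
    # distinct physical acquisitions would add slice-sampling variability
    ratios = [r + float(rng.normal(0, 1.0)) for r in ratios]
    groups.append(GroupSample(label, tuple(ratios)))

for g in groups:
    norm = shapiro_wilk(g.values)
    print(f"{g.label:9s} mean ratio {g.mean:5.1f}%  "
          f"Shapiro-Wilk W={norm.W:.3f} p={norm.p_value:.3f}")

anova = welch_anova(groups)
print(f"\nWelch ANOVA: F={anova.F:.2f} df=({anova.df1:.0f}, {anova.df2:.1f}) "
      f"p={anova.p_value:.2e}")

print("\nGames-Howell pairwise comparisons:")
for c in games_howell(groups):
    mark = "*" if c.significant_at_05 else " "
    print(f"  {c.group_a:9s} vs {c.group_b:9s} diff={c.mean_diff:6.1f} "
          f"p={c.p_adjusted:.4f} {mark}")
# A significant omnibus F with the 'gold' group separating from every
# other group mirrors the qualitative pattern a strong MAR responder shows.
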