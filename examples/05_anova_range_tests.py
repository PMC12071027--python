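"""Type III ANOVA and Fisher LSD range tests with known ground truth.

Injects a +0.05 macro-F1 advantage for one level of the top-instance factor
(Nt = 5) into a synthetic 864-run results table, then shows that the
main-effects Type III ANOVA flags exactly that factor and that the LSD
multiple-range test isolates the responsible level with its own group letter.
"""

from milanova import (
    EffectSpec,
    FactorLevels,
    fit_main_effects,
    generate_results_table,
    homogeneous_groups,
    ls_means,
    lsd_contrasts,
    type3_anova,
)

grid = FactorLevels(replicates=3)
effects = EffectSpec(
    factor_effects={"Nt": {5: 0.05}},  # one level raised; centered over the grid
    baseline=0.6,
    noise_sd=0.01,
)
table = generate_results_table(grid, effects, seed=3)

fit = fit_main_effects(table, "F1", ["Wd", "Ly", "Dp", "Nt", "Nb"])
anova = type3_anova(fit)
print("Type III ANOVA for F1:")
print(anova.to_string(index=False, float_format=lambda v: f"{v:.5g}"))

print("\nLS means and homogeneous groups for Nt (alpha = 0.05):")
means = ls_means(fit, "Nt")
contrasts = lsd_contrasts(fit, "Nt")
letters = homogeneous_groups(means, contrasts)
for m in means:
    print(
        f"  Nt={m.level:>2}: mean={m.mean:.4f} +- {m.se:.4f} "
        f"[{m.lower:.4f}, {m.upper:.4f}]  group '{letters[m.level]}'"
    )
print("(only the injected factor has p < 0.05; Nt=5 carries its own letter)")
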