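"""Screen gross failures out of a results table before ANOVA.

Builds a full 288-cell x 3-replicate synthetic results table, injects three
gross training failures (AUC ~0.5, chance level), and screens with the hard
adequacy thresholds AUC >= 0.65 and F1 >= 0.45.  Also demonstrates the three
univariate statistics that document each exclusion: studentized z-scores,
MAD-based modified Z-scores, and Grubbs' test.
"""

from milanova import (
    EffectSpec,
    FactorLevels,
    generate_results_table,
    grubbs,
    modified_zscores,
    screen_results,
    zscores,
)

sample = [1, 2, 3, 4, 100]
print(f"sample {sample}:")
print(f"  z-scores            : {zscores(sample).round(3).tolist()}")
print(f"  modified Z (MAD)    : {modified_zscores(sample).round(3).tolist()}")
res = grubbs(sample)
print(
    f"  Grubbs: t_max={res.t_max:.3f}, p={res.p_value:.4f} "
    f"-> index {res.index} {'IS' if res.outlier else 'is NOT'} an outlier"
)

grid = FactorLevels(replicates=3)
effects = {
    "F1": EffectSpec(baseline=0.63, noise_sd=0.01),
    "AUC": EffectSpec(
        baseline=0.85, noise_sd=0.01,
        outlier_rows=[(17, 0.50), (333, 0.52), (789, 0.48)],  # chance-level runs
    ),
}
table = generate_results_table(grid, effects, seed=6)
filtered, report = screen_results(table, auc_min=0.65, f1_min=0.45)
print(f"\nscreen: {report.n_before} runs -> {report.n_after} survive")
print(report.rows[["row", "metric", "value", "modified_z", "reason"]].to_string(index=False))
print("(the injected chance-level runs are exactly the ones removed)")
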