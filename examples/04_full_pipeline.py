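"""Run the full cross-validated experiment on a synthetic survey population.

Per training fold: weight-of-evidence encoding, stability feature selection,
then the GMDH network and an LDA baseline on identical test folds; the
rendered report mirrors the per-fold, pooled-with-CI95 and comparison
layouts.
"""

from gmdhscreen.pipeline import ExperimentConfig, render_report, run_experiment
from gmdhscreen.preprocessing import StabilitySelectionConfig
from gmdhscreen.synthetic import survey_generator_config

config = ExperimentConfig(
    data=survey_generator_config(n_subjects=4_000, seed=11),
    outcomes=("worriedness", "depression"),
    classifiers=("gmdh", "lda"),
    k=3,
    seed=11,
    stability=StabilitySelectionConfig(n_subsamples=30, seed=11),
)
bundle = run_experiment(config)
print(render_report(bundle))
# Reading the report: Se/Sp/Pr/Acc rows are percents (pooled rows carry
# Wilson 95% CIs); DOR is the diagnostic odds ratio, DP its discriminant
# power, MCC the Matthews correlation; the comparison block reports
# Cochran's Q and Bonferroni-adjusted pairwise McNemar p-values on the
# shared test folds.
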