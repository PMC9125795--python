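"""Validate the four measures against (synthetic) rater labels.

Generates labeled pairs whose similar/discrepant rating is a noisy logistic
function of true taxonomic distance, scores them with all four measures and
prints each measure's AUC with its 95% DeLong confidence interval and the
p-value against the coin-flip null (AUC = 0.5).
"""

from icdsim import FixtureSpec, LabelModel, generate_labeled_pairs, generate_taxonomy
from icdsim.similarity import score_pairs
from icdsim.validation import summarize_dataset, validation_report

spec = FixtureSpec(n_pairs=1000, label_model=LabelModel(1.5, 4.0, noise_seed=7))
taxonomy = generate_taxonomy(spec)
pairs = generate_labeled_pairs(taxonomy, spec)
scored = score_pairs(taxonomy, pairs)

summary = summarize_dataset(scored)
print(
    f"{summary.n_pairs} pairs, {summary.n_discrepant} rated discrepant "
    f"(error prevalence {summary.prevalence_percent:.2f}%)"
)
print()
report = validation_report(scored)
print(report[["algorithm", "auc", "ci_low", "ci_high", "p_value_vs_half"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("All four measures rank discrepant above similar pairs far better than")
print("chance; on leaf-level pairs they are monotone transforms of the same")
print("path length, so their AUCs coincide.")
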