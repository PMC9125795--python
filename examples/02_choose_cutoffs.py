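"""Derive similar/discrepant cutoffs for a target sensitivity.

Generates a synthetic labeled validation set, sweeps every candidate
threshold for the steps distance and picks the cutoff that guarantees
sensitivity 1.0 (the trigger-for-review setting: miss no labelling error,
accept false alarms), then a specificity-0.9 cutoff (the assessment
setting: few false "error" calls at the cost of missed ones).
"""

from icdsim import FixtureSpec, LabelModel, generate_labeled_pairs, generate_taxonomy
from icdsim.classification import cutoff_for_target, sweep_cutoffs
from icdsim.similarity import Algorithm, score_pairs

spec = FixtureSpec(n_pairs=500, label_model=LabelModel(1.5, 4.0, noise_seed=42))
taxonomy = generate_taxonomy(spec)
pairs = generate_labeled_pairs(taxonomy, spec)
scored = score_pairs(taxonomy, pairs, [Algorithm.STEPS])

sweep = sweep_cutoffs(scored["steps"], scored["label"], Algorithm.STEPS)
print("Candidate cutoff sweep for the steps distance (head and tail):")
print(sweep.head(3).to_string(index=False))
print("...")
print(sweep.tail(3).to_string(index=False))
print()

for target in ({"sensitivity": 1.0}, {"specificity": 0.9}):
    rule, sens, spec_ = cutoff_for_target(
        scored["steps"], scored["label"], Algorithm.STEPS, **target
    )
    print(
        f"target {target}: classify as discrepant if steps >= {rule.threshold:g} "
        f"-> sensitivity {sens:.2f}, specificity {spec_:.2f}"
    )
print()
print("The sweep's end rows are the sentinels: a threshold below every")
print("observed score calls everything discrepant (sensitivity 1, specificity")
print("0) and one above calls nothing discrepant; interior thresholds are")
print("midpoints between consecutive observed scores.")
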