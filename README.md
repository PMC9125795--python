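# icdsim

Taxonomy-based similarity of ICD-coded diagnosis pairs, and an automated
trigger for diagnostic labelling errors built on it.

A diagnostic *labelling* error is naming a disease A when the more
definitive diagnosis is B — for instance an emergency-room admission
diagnosis that disagrees with the internal-medicine discharge diagnosis.
Identifying such discrepancies normally requires panels of expert raters,
which is slow, small-scale and bias-prone. When both diagnoses are coded in
an ICD-style classification (routinely the case in health-care data), their
discrepancy can instead be *computed* from the classification tree itself
and used as an e-trigger that flags cases for review. `icdsim` is for
diagnostic-safety researchers, quality managers and assessment researchers
who have pairs of ICD-coded diagnoses and want an automated, tunable
similar/discrepant classifier plus the machinery to validate it against
their own rater-based reference standard.

## The measures

The ICD is a uniaxial classification: chapters contain disease groups,
groups contain three-character categories, categories contain four-digit
codes. With a synthetic root above the chapters it is a rooted tree, on
which four structural measures are defined for a pair of diagnoses
(a, b) with least common subsumer (most specific common ancestor) *lcs*:

| measure | formula | orientation |
|---|---|---|
| steps | shortest-path edge count = depth(a) + depth(b) − 2·depth(lcs) | distance |
| weights | sum of level-dependent edge weights on that path | distance |
| WuPalmer | 2·depth(lcs) / (depth(a) + depth(b)) | similarity in [0, 1] |
| Lietal | e^(−α·steps) · tanh(β·depth(lcs)) | similarity in [0, 1) |

Depth is counted in edges from the root. The default weight scheme doubles
per level (chapter edges 8, group 4, category 2, code 1), so cross-chapter
confusions accumulate much larger distances than within-chapter ones; the
default Li et al. parameters are α = 0.2, β = 0.6.

Scores are dichotomized by a cutoff rule — discrepant if a distance is
**≥** the threshold, or a similarity is **≤** it — and the cutoff achieving
any target sensitivity or specificity is selected from the sweep of
midpoints between observed scores (plus sentinels outside the range).
Validation against rater labels uses ROC analysis: trapezoidal AUC
(equivalently the Mann–Whitney statistic with ties at half credit), 95%
confidence intervals from the DeLong variance estimate, and a z-test
against the coin-flip null AUC = 0.5.

## Worked example

```python
import io, pandas as pd
from icdsim import load_taxonomy, score_pairs

taxonomy = load_taxonomy("my_icd.tsv")          # or format="claml"
pairs = pd.DataFrame({
    "pair_id": ["identical", "sibling-codes", "cross-chapter"],
    "code_a": ["E10.1", "E10.1", "E10.1"],
    "code_b": ["E10.1", "E10.9", "C18.9"],
})
print(score_pairs(taxonomy, pairs))
```

On the miniature two-chapter tree of `examples/01_score_pairs.py` this
prints:

```
      pair_id code_a code_b  steps  weights  wupalmer   lietal
    identical  E10.1  E10.1    0.0      0.0      1.00 0.983675
sibling-codes  E10.1  E10.9    2.0      2.0      0.75 0.634663
cross-chapter  E10.1  C18.9    8.0     30.0      0.00 0.000000
```

Sibling four-digit codes are 2 steps apart (up to the shared category and
back down) with Wu-Palmer 2·3/(4+4) = 0.75; a cross-chapter pair travels 8
edges through the root, where the shared depth — and with it both
similarity measures — collapses to 0. Note that Li et al. scores an
identical pair tanh(0.6·4) ≈ 0.984, not exactly 1: the published formula is
kept without an identity special case.

The `examples/` directory continues from here: choosing cutoffs for a
target sensitivity or specificity (`02`), the ROC/AUC validation report
(`03`) and the signal-strength knob of the synthetic data generator (`04`).
A thin CLI wraps the same library:

```sh
icdsim fixture --n-pairs 500 --seed 3 --taxonomy-out tax.tsv --pairs-out pairs.tsv
icdsim validate --taxonomy tax.tsv --pairs pairs.tsv --cutoff-table-out cutoffs.tsv
icdsim cutoffs --taxonomy tax.tsv --pairs pairs.tsv --algorithm steps --sensitivity 1.0
```

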