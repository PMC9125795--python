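# Methods

## The classification tree

An ICD-style classification is treated as a rooted tree with five levels:
a synthetic `ROOT` (the ICD itself has no single top node), chapters,
groups, three-character categories and four-digit codes. Depth is counted
in **edges from the root**, so `depth(ROOT) = 0` and a four-digit code on a
full branch has depth 4. Branches may terminate early (a category without
four-digit children is a legal leaf). The loader accepts a generic
tab-delimited edge list (`code  parent  level  label`) as the canonical
format — so ICD-9, ICD-10, national modifications and toy trees are all
handled identically — and ClaML, the XML dialect of official ICD releases,
as a convenience reader. Chapters may be keyed by Roman numeral or letter
range; the loader takes whatever the source uses, verbatim.

Code lookup normalizes case, whitespace and the dot between the third and
fourth character (`e10.1` → `E101`). A code more specific than anything in
the tree (say a five-digit national-modification code against a four-digit
catalogue) is truncated one character at a time until an ancestor matches
and is scored at that ancestor, with the truncation recorded in the output.
In batch scoring, unresolvable codes flag their row and are logged, never
fatal — routine data always contain a few.

## The four measures

All four are functions of the pair's depths and their least common
subsumer (LCS); because the taxonomy is a tree, the shortest path
decomposes exactly through the LCS, and no graph search is needed (the
BFS/Dijkstra equivalence is property-tested against networkx on random
trees, but the implementation is closed-form).

* **steps** — shortest-path edge count; integer distance, 0 iff identical.
* **weights** — the same path with level-dependent edge weights. The
  published description fixes only the principle (chapter-level edges
  outweigh within-chapter edges), not the values; the default here doubles
  per level — (root,chapter) = 8, (chapter,group) = 4, (group,category) = 2,
  (category,code) = 1 — and is fully configurable. With all-ones weights
  the measure reduces exactly to steps.
* **WuPalmer** — `2·depth(lcs) / (depth(a)+depth(b))`. With the edge-depth
  convention the root contributes no shared depth, so cross-chapter pairs
  score exactly 0; identical non-root pairs score exactly 1. The root
  paired with itself (0/0) is a domain error.
* **Lietal** — `exp(−α·steps) · tanh(β·depth(lcs))`. The source formula's
  optimal parameters α = 0.2, β = 0.6 are the defaults, overridable in
  config. The formula is kept **without** an identity special case: two
  equal codes at depth 4 score tanh(2.4) ≈ 0.9837, not 1. Patching identity
  to 1 would break the formula's monotone dependence on subsumer depth, so
  the published form is preserved and documented instead.

Whether the original web implementation of this trigger counts depth in
nodes or edges is not published; anyone comparing raw score values against
a hosted service should check that convention first. AUC-based validation
is unaffected, since the two conventions differ by a monotone transform.

## Cutoffs

A cutoff rule calls a pair discrepant when a distance-type score is
**larger or equal to** the threshold, or a similarity-type score is
**smaller or equal to** it (non-strict comparison in both directions,
following the tabulated cutoff convention rather than the looser running
prose "below which"). Candidate thresholds are the midpoints between
consecutive distinct observed scores, plus sentinels at `min − 1` and
`max + 1`, so the sweep always contains the two degenerate operating points
(everything discrepant: sensitivity 1/specificity 0; nothing discrepant:
sensitivity 0/specificity 1). For a requested sensitivity (or specificity)
bound, the selected cutoff is the one with the **smallest achieved value
meeting the bound**; ties are broken by maximizing the complementary
metric, then by proximity to the observed-score midrange — deterministic
by construction.

## Validation statistics

AUC is computed from placement values (midranks), which is identical to
trapezoidal integration of the empirical ROC curve and to the Mann–Whitney
statistic with ties given half credit; the curve itself comes from
scikit-learn with no intermediate-point dropping. Similarity-type scores
are negated before ranking so "larger = more discrepant" holds uniformly.
The 95% CI uses the DeLong structural-component variance with a normal
approximation truncated to [0, 1]; the original analysis was run in a
commercial statistics package whose CI method is unstated, so third-decimal
differences against it are possible. The test against AUC = 0.5 is a
two-sided z-test on the same variance, with p = 1 by convention when the
variance is 0 at AUC exactly 0.5 (all scores tied). Dataset summaries
report error prevalence as `100·n_discrepant/n_pairs`, rounded half-up to
two decimals; recomputing the published validation cohorts' prevalences
from their class counts gives 12.32% and 87.16% where the source prints
12.30%/87.20% — the computed values are reported, the tiny rounding
discrepancy is documented rather than reproduced. Coder agreement uses
Cohen's kappa, with the `p_e = 1` case (both raters constant and equal)
signalled as undefined rather than returned as NaN.

## Synthetic data

The generator emulates, at desk scale, a rater-labeled validation dataset:
a regular four-level tree (defaults: 2 chapters × 4 groups × 4 categories ×
4 codes = 171 nodes, 128 leaves) and `n_pairs` pairs drawn uniformly over
leaf codes, labeled discrepant with probability
`sigmoid(slope · (steps − midpoint))`. The logistic-in-distance link is the
simplest generative story consistent with taxonomic distance tracking
expert discrepancy ratings; `slope` (default 1.5 per step) is the
signal-strength knob — 0 yields chance-level AUC, very large values label
by thresholding the distance exactly and yield AUC 1 — and `midpoint`
(default 4 steps) sets where raters flip. A single integer seed drives all
randomness; identical specs give byte-identical outputs.

The default tree shape was chosen by computing, from the leaf-distance
distribution and the logistic link, the expected steps AUC under the
default label model across plausible shapes, and taking the shape whose
operating point (≈ 0.93, pilot range 0.91–0.95 over 20 seeds at n = 1000)
sits inside the 0.80–0.95 band that validation studies of this trigger
report. Two things the synthetic data deliberately do **not** reproduce:
(i) uniform leaf sampling makes ~90% of pairs discrepant — the regime of a
high-error educational dataset, not of clinical admission/discharge pairs
where most pairs are similar (AUC, being prevalence-independent, is
unaffected; prevalence-sensitive quantities like predictive values would
be); (ii) both members of a pair are always four-digit leaves, so all four
measures become monotone transforms of one path length and their AUCs
coincide exactly — mixed-level pairs, where the measures genuinely diverge,
are exercised by dedicated unit tests instead. Passing tests on this
generator therefore demonstrate correct machinery and signal recovery, not
clinical performance.

## Numerical and scale choices

Tolerances: closed-form similarity checks at 1e−9 or tighter; AUC oracle
equivalence at 1e−12; stochastic checks (chance-level AUC ± 0.05 at
n = 2000, DeLong coverage within [0.92, 0.98] over 1000 replicates at
n = 100/100 per class) at fixed seeds. Property suites use random leveled
trees of up to 200 nodes with ≥ 500 oracle-checked pairs. The acceptance
script's problem sizes (400–2000 pairs, 1000 Monte-Carlo replicates) were
chosen so each quantity's Monte-Carlo error is well inside the band it is
checked against.

## Known limitations

* Single-diagnosis pairs only; comparing two *sets* of diagnoses is out of
  scope, as is free-text-to-ICD coding and any mapping between ICD
  revisions.
* No information-content (corpus-frequency) similarity measures — the
  trigger is purely structural.
* No cost-weighted threshold optimization (Youden index etc. can be layered
  on top of the sweep but are not provided).
* The DeLong interval degenerates to [1, 1] at perfect separation; with
  very small class counts its coverage is known to be anti-conservative.
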