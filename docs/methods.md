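# Methods

## The model

`igensig` predicts a binary therapeutic endpoint (pCR vs non-pCR) from a
binary patients × features incidence matrix. It is a white-box,
integral-signature model: every feature passing a univariate association
cutoff contributes to the score, and multicollinearity is handled by an
explicit, per-patient redundancy penalty rather than by feature
selection.

**Weights.** The weight of feature *i* is its phi coefficient with the
response — the Pearson product-moment correlation of two 0/1 vectors,
computed exactly from the 2×2 contingency table. Features with
|ω| ≥ `cutoff` (default 0.13) are retained; the sign partitions them
into a *sensitive* (ω > 0) and a *resistant* (ω < 0) class. Constant
features get ω = 0 (harmless; never retained). No multiple-testing
control is applied: the method deliberately keeps a large, redundant
significant set rather than a sparse corrected one.

**Redundancy penalty.** Feature co-occurrence is estimated on an
unlabeled reference cohort as the Otsuka–Ochiai (cosine set) coefficient
K<sub>ij</sub> of the two carrier sets. For each patient and class, the
carried retained features are clustered (see *Cluster gating*) and each
feature's penalty is

  ε<sub>i</sub> = Σ<sub>j same cluster</sub> K<sub>ij</sub>  (including j = i, so ε<sub>i</sub> ≥ 1).

ε<sub>i</sub> estimates how many effective copies of feature *i* the
patient carries: 1 for an isolated feature, k for k exact duplicates.
Features with no reference carriers are treated as non-redundant
(K<sub>ii</sub> = 1, K<sub>ij</sub> = 0), so their penalty degrades
gracefully to 1.

**Score.** With EW<sub>i</sub> = |ω<sub>i</sub>|/ε<sub>i</sub> and
EFN = Σ<sub>i</sub> 1/ε<sub>i</sub>, the class score is Σ EW<sub>i</sub> / EFN.
EFN is the effective feature number — equivalently n divided by the
*harmonic* mean penalty. Two exact consequences (both under test):
with an all-orthogonal reference the score is the plain mean |ω| of the
carried class features, and replacing every feature by k identical
copies (in the labeled and the reference cohort alike) changes nothing.
We use the harmonic-mean (sum-of-reciprocals) form of EFN rather than
n over the arithmetic mean penalty: the two coincide under homogeneous
penalties, but with mixed penalties the arithmetic form counts an
isolated feature as 1/ε̄ ≪ 1 effective features, which can invert the
ranking of patients who differ in how many redundant blocks they carry.
The harmonic form keeps the score a proper weighted mean (weights
1/ε<sub>i</sub>) of the |ω|.

**Decision rule.** Scoring yields a (resistant R, sensitive S) pair per
patient. On training data the D-line S = m·R through the origin is
chosen to maximize the Youden index J = TPR − FPR of the rule
"sensitive iff S > m·R" over an angle grid θ ∈ {0.5°, 1°, …, 89.5°}
(resolution configurable; ties go to the smallest angle). The final
score is the signed perpendicular distance (S − mR)/√(1+m²); patients
above the line (positive score) are called sensitive. With all-identical
training scores the slope defaults to 1 with a warning.

**Leave-one-out training scores.** When a training patient is scored —
including the scores the D-line is fitted on — the weight table is
recomputed with that patient excluded (a fast contingency-count update).
This prevents the patient's own label from inflating its score; external
cohorts are scored with the full-cohort weights. The feature universe
(pruning) is fixed by the full cohort; only the weights and retention
flags are re-derived per held-out patient.

## Feature derivation and pruning

Continuous expression becomes nested binary features at twelve
stringency levels per direction. Percentiles are within-cohort average
ranks scaled to (0, 100]; the default cutoffs are evenly spaced
(Up ≥ 52, 56, …, 96; Down ≤ 48, 44, …, 4) and configurable via YAML.
Nesting is cumulative — membership at level k+1 implies level k — which
intentionally manufactures redundancy for the penalty to absorb. Variant
tables yield one feature per mutated gene (`MUT:`) or adjacent gene
rearrangement (`AGR:`).

Two pruning rules: level-1 features are removed (the weakest calls,
carried by nearly half the cohort, contribute mostly noise), and any
gene whose retained Up and Down features predict response with the same
sign has *all* its expression features removed (gene-level
inconsistency). Whether percentiles should be computed within-cohort or
against an external reference distribution is an open modeling question;
within-cohort is used because it is self-contained and rank-based.

## Cluster gating

The penalty must not accumulate small incidental overlaps across
unrelated features, so coefficients outside a feature's own cluster are
excluded. Clustering is recomputed per patient (the penalty is defined
on the redundancy *that patient* carries) on d = 1 − K with Ward
linkage (scipy's `ward`, the ward.D2 variant on a precomputed
distance). Labels come from a self-contained dynamic hybrid tree cut:

* merges are replayed bottom-up; at each join, a branch stands alone as
  a cluster if it has ≥ `min_cluster_size` (default 2) members, its mean
  within-branch dissimilarity (core scatter) is ≤ 0.82, and the gap
  between cross-branch and within-branch mean dissimilarity is ≥ 0.135;
  otherwise the branches fuse and growth continues;
* the scatter/gap thresholds follow the dynamic-tree-cut family's
  deepSplit interpolation (deepSplit 2 → max core scatter 0.82,
  min gap = (1 − 0.82)·3/4); deepSplit is configurable 0–4;
* merges above 99% of the top merge height never fuse (static cut);
* members with zero similarity to the rest of their cluster, and
  branches below the minimum size, become singletons, so every feature
  is labeled and ε ≥ 1 always holds.

One deliberate deviation from a naive port of the reference tree-cut
implementation: scatter and gap are measured on the bounded [0, 1]
dissimilarity scale, not on Ward's unbounded merge heights. Ward heights
grow with branch size, so height-based thresholds scale with the tree
top and collapse block-structured data into one or two giant clusters;
on the dissimilarity scale the same deepSplit thresholds recover planted
blocks correctly (under test against transitive-block oracles).

## Synthetic study design

Real cohorts in this problem domain are controlled-access, so the
package generates synthetic ones that reproduce the two structures the
method exploits: *feature redundancy* and *transferable co-occurrence*.
Features come in blocks; per patient, each block has a latent Bernoulli
driver, and every feature in the block copies the driver with
independent flip noise. An unlabeled reference cohort is drawn from the
same block model without labels. Predictive blocks tie the driver to the
response; half are oriented toward resistance (carriage pair swapped),
because the model scores a sensitive *and* a resistant axis and a cohort
with signal on only one axis resembles no real trial.

Defaults (the study conditions for all power-sensitive tests):
200 patients with balanced labels (the training trial this emulates is
~109 vs 108), 1,000 reference tumors, 40 blocks × 25 features, 8
predictive blocks with carriage 0.7 given pCR vs 0.2 given non-pCR
(|phi| ≈ 0.45 in expectation, comfortably above the 0.13 cutoff), 30%
background driver rate, 5% feature flip noise. Flip noise keeps
within-block Ochiai ≈ 0.9 (blocks are redundant but not degenerate)
while staying at the bottom of the 5–25% range the error-robustness
protocol injects *on top*.

What the synthetic study does **not** show: cross-dataset transfer
(there is one cohort distribution, not four trials on different
platforms), intensity-graded signal (real nested expression levels give
stronger responders higher-weight features; flat blocks encode signal
only in block counts), batch effects, and realistic sparsity patterns
of mutation data. Passing tests demonstrate the machinery — recovery of
planted signal, correct penalization, chance-level behavior under label
permutation, robustness to feature dropout — not clinical performance.

## Error simulation and robustness

`inject_errors` corrupts a matrix in one direction at a time:
false negatives clear each set bit with probability `rate`; false
positives set clear bits with probability normalized so the expected
number of *added* bits is `rate` × current set bits (binary genomic
matrices are sparse; flipping 25% of zeros would not resemble miscalls).
The robustness experiment injects errors into the training or the
validation side, retrains/rescores per rate and error seed, and compares
against an L1-logistic (lasso) baseline whose penalty is chosen by
internal cross-validation.

The default protocol is validation-side false negatives — feature loss,
the mechanism redundancy is designed to absorb — and there the integral
score's AUROC is flat across 0–25% while the lasso baseline degrades.
A transparent limitation: under heavy false-*positive* flooding the
comparison reverses on this synthetic study, because lasso's sparse
support is rarely hit by random added bits while the integral score
admits every retained spurious feature; and because a single
same-distribution cohort leaves lasso near ceiling (AUROC ≈ 1.0),
unlike the cross-dataset regime where sparse models are reported to
destabilize.

## Numerical and engineering choices

* Weights, scores and similarities are plain float64; phi is computed
  from exact integer contingency counts.
* The angle grid at 0.5° is much finer than any Youden plateau at
  cohort sizes of a few hundred; the tie-break (smallest angle) makes
  the fit deterministic.
* Weight tables serialize at 6 decimals; similarity triplets at 10
  significant digits (upper triangle, zeros omitted). Artifact
  round-trips therefore reproduce scores to ~1e-6, and a freshly saved
  and loaded model is under test for scoring equivalence.
* Stratified 90/10 splits (rather than plain random sampling) guarantee
  both classes in a 10%-test set at n ≈ 200.
* Empty cases are defined, not exceptional: a patient with no retained
  class features scores 0 for that class; an all-zero patient scores
  (0, 0), sits below any D-line, and is called non-sensitive.
* Determinism: every stochastic step takes a seed, and the CLI threads a
  single `--seed` through generation, splitting and error injection;
  identical invocations are byte-identical.
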