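# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the places where the design was genuinely open.

## Binding similarity model

The core object is a classifier over *pairs* of compounds. A pair is
labelled positive at an annotation level (motif, domain, family,
superfamily — configurable; the synthetic universe uses family and
superfamily) when the two compounds' targets are identical or share at
least one annotation label at that level. Relatedness is deliberately
binary: sharing several labels does not strengthen it, and an empty label
set at a level leaves a target related only to itself.

**Pair featurization.** For fingerprints f_a, f_b of length L the feature
vector is the concatenation of the elementwise AND block (bits the pair
shares) and the elementwise XOR block (bits on which they differ), length
2L. Both blocks are symmetric in (a, b), so pair scores are
order-invariant by construction. Alternate layouts can be supplied by
featurizing externally; the AND/XOR default preserves both shared-feature
and difference information without imposing a metric.

**Level classifiers.** The default learner is a bagged decision-tree
ensemble (scikit-learn random forest, 100 trees, `min_samples_leaf=2`,
fixed seed) behind a pluggable factory; the contract is only a calibrated
probability in [0, 1]. Training pairs at a level are all ERCP-positive
pairs of actives (optionally subsampled to a configurable cap, default
2000, to bound training cost) plus, for every active, four background
partners drawn without replacement within that active's draw — molecules
forming an ERCP with the active at that level are excluded from the draw,
so negatives are not merely random but verifiably unrelated at the level
being learned.

**Stacking.** Per-level scores are combined by a logistic regression. To
keep the stacker's inputs out-of-sample, pairs are split (stratified,
seeded) into a level-training part and a held-out stacking part (default
25%); leakage is enforced both by split tags and by an explicit pair-key
audit that raises rather than warns. A stacking pair counts as positive
when it is an ERCP at *any* configured level — the union reading; the
per-level labels are all computed at pair-construction time, so other
conventions can be derived from the stored labels.

**Target-specific restriction.** For a VS target t, the ERCP definition at
each level is intersected with the targets related to t at that level, so
every positive pair is evidence about binding in t's evolutionary
neighbourhood. The model stores t's known actives (after affinity
filtering) as references; a query's score is the maximum pair score over
references, with ties resolved to the lexicographically smallest reference
id, and queries whose canonical key equals a reference's are flagged (not
silently dropped). Training warns — advisorily, not fatally — when the
target has fewer than 10 actives. Candidate selection keeps scores at or
above the cutoff (inclusive; the default 0.7 follows the screening
convention the package implements).

## Benchmarks and metrics

An interaction is *active* when any of its Ki/IC50/Kd/EC50 measurements is
strictly below 100 nM; the four types are treated disjunctively, and all
records of a kept (molecule, target) pair are retained, which makes the
filter idempotent. The pairwise benchmark takes all unordered pairs of
actives bound to common or related targets as positives and four
background partners per active as negatives; the pointwise benchmark emits
each active plus four labelled background molecules.

PR AUC is computed as step-wise average precision, Σ (R_i − R_{i−1})·P_i
over thresholds swept from the highest score down with tied scores grouped
into a single threshold; trapezoidal interpolation is avoided because it
overestimates PR area. ROC AUC uses the trapezoid rule, which under the
same tie-grouping equals the Mann–Whitney statistic. Both implementations
are property-tested against brute-force threshold-enumeration oracles (and
cross-checked against scikit-learn) on every random instance of ≤ 12
items, and are invariant under strictly monotone score transforms.

## Synthetic chemogenomic universe

The generator provides ground truth for everything the benchmarks cannot
get from real data at desk scale. Targets form a nested hierarchy
(default: 2 superfamilies × 2 families × 3 targets). Each family owns a
disjoint block of 16 *latent* fingerprint bits — the binding determinant.
Every molecule, active or background, carries one of 12 shared *scaffold*
patterns (40 bits drawn from the non-latent positions) plus independent
base bits at density 0.10; actives additionally carry their family's
latent block; finally every bit is flipped independently with probability
0.05. Fingerprints are 256 bits, a MACCS/FP4-scale representation.

The scaffold pool is the load-bearing design choice: background molecules
that share a scaffold with a reference active are structurally similar
without binding (the activity-cliff regime), and held-out binders on
scaffolds absent from the references are structurally dissimilar (scaffold
hopping). Without it, pure-noise background is trivially separable by raw
Tanimoto similarity and the comparison between methods is vacuous. What
the universe does *not* emulate: real chemical-space statistics, correlated
fingerprint bits, assay batch effects, or targets whose annotation levels
fail to nest — so passing tests demonstrate that the machinery recovers
planted structure under the stated noise model, not field performance.

Active affinities are drawn log10-normally (μ = 1.0, σ = 0.7 in log10 nM)
rejected above 100 nM, so every generated active survives the affinity
filter by construction; 10% of actives additionally receive a promiscuous
off-target record in [100 nM, 10 µM], which the filter must remove.
Dose-response curves are generated from the same Hill model the fitter
assumes, POC(c) = 100/(1 + (c/Kd)^h), with multiplicative Gaussian noise.

Hold-out evaluation trains on two-thirds of a target's actives and splits
the background pool in half between training negatives and test negatives,
so no molecule appears on both sides. The headline comparison (5 seeds, 2
VS targets per seed — one per superfamily) takes ~10 s per seed on one
CPU; sizes were chosen so the full suite and the acceptance script run
comfortably on a laptop-class machine.

## Activity modeling

**POC → activity.** activity = 100 − POC; readouts outside [0, 100] pass
through with a warning since assay noise can produce them.

**Hill fit.** Least squares in log-dose space with Kd parameterized as
log10(Kd); h bounded to [0.2, 5] and top/bottom free within [−10, 120] POC
units (robustness to assay drift). Initialization takes log10(Kd) from the
dose whose response is closest to the data midpoint; an explicit starting
point can be supplied for basin checks. At least 4 distinct doses are
required, constant responses are a hard error ("no signal"), and optimizer
failure is reported via `converged=False` rather than masked.

**Uncertainty and rescaling.** An activity a with multiplicative
uncertainty u ≥ 1 is trusted to lie in [a/u, a·u]. Before fitting, raw
activities are affinely rescaled in log10 space so max/min = 10^4
(anchored at min → 1), preserving rank order.

**QSAR surrogate.** The pharmacophore-hypothesis search of commercial
QSAR tools is replaced by a transparent weighted ridge regression on
log10(activity) over descriptor vectors; geometric feature hypotheses are
out of scope. Weights are w = 1/(1 + log10 u)², so a point interval
(u = 1) weighs 1 and a decade of uncertainty weighs 0.25. The ridge
penalty (default 1e-6) exists to keep rank-deficient fits well-posed; on
well-conditioned problems it leaves exact linear relationships recoverable
to < 1%.

**Fisher randomization.** Model quality at confidence level L ∈ {90, 95}
is assessed by refitting after permuting the activity labels
⌈100/(100−L)⌉ − 1 times (9 and 19 permutations respectively) and requiring
the true fit's score to strictly exceed every permuted score. A
permutation whose fit fails is counted as beating the model — the
conservative direction. With a continuous score this yields a type-I error
of 1/(n_perm + 1); the test suite verifies ~5% at the 95% level over 500
null simulations. The default score is the training-set Pearson
correlation, which is exchangeable under permutation; a cross-validated
correlation is also provided for negative controls.

**Combined decision.** prioritize iff similarity ≥ score cutoff (default
0.7) AND predicted activity ≥ activity cutoff (default 50 on the 100−POC
scale, i.e. predicted POC below 50); both comparisons inclusive. The
pipeline applies the rule only to rows with both scores present.

## Pipeline

The integrated run persists every stage (scores, candidates, assay table,
report, manifest) so it can be audited; the manifest records a hash of the
configuration and the seed, and identical configuration reproduces the
report byte for byte. When no measured assay is supplied, the assay stage
can be simulated from ground truth: true binders get Kd log-uniform in
[1 µM, 10 µM] and a POC evaluated at a 10 µM screening concentration;
non-binders read out near full control (POC 85–100). Requesting the
secondary tier without assay data degrades to a warning and a
primary-only report, never a silent skip. Hit rates are reported as
100·n_active/n_tested rounded to one decimal, with a compound counted
active when its 100−POC activity passes the rule (default threshold 65,
i.e. POC below 35).

## Known limitations

- The per-level learner's in-sample separation diagnostic (recorded in
  `training_meta`) is optimistic for tree ensembles; generalization claims
  in the tests always use held-out pairs.
- The QSAR surrogate is linear in the descriptors; it stands in for
  hypothesis-based 3D methods only at the level of its activity,
  uncertainty, rescaling and validation semantics.
- Fingerprint-native synthetic molecules have no structures, so canonical
  keys for them are fingerprint hashes; InChIKey-based deduplication
  applies only to parsed structures.
- With very few assayed compounds (< 4) the secondary tier is skipped;
  with few but sufficient compounds the ridge fit can interpolate the
  assay, making the combined decision lean on the similarity cutoff.
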