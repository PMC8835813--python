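# Methods

## Problem and model

`stressmir` frames stress-responsiveness prediction as balanced binary
classification of short RNA sequences. The only inputs are the sequences
themselves (mature miRNA, precursor, or both), so the model's working
assumption is that compositional and short-range order signal in the
sequence — k-mer usage plus physicochemical autocorrelation — carries
information about whether a miRNA participates in abiotic stress response.
Nothing about secondary structure, expression, or targets is modeled.

## PseKNC encoding

Each sequence is encoded per tuple size K into 4^K normalized overlapping
k-mer frequencies (window step 1; absent k-mers are explicit zeros) plus λ
correlation factors δ_j, j = 1..λ. δ_j averages, over all window pairs j
positions apart, the mean squared difference of R standardized property
values between the two tuples. The weighted assembly
θ = (g, ωδ) / (Σg + ωΣδ) makes every K-block a composition (non-negative,
sums to 1), which the tests enforce to 1e−9.

Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| K values | 2, 3, 4, 5 | tuple sizes; blocks of 19/67/259/1027 features, 1372 total |
| λ | 3 | correlation tiers; short mature sequences (≥ 20 nt) support only a few tiers, and the minimum encodable length is max(K)+λ = 8 |
| ω | 0.2 | weight of correlation entries relative to frequencies |

λ and ω are shared across K-blocks. The minimum length is enforced rather
than silently shrinking the feature space per sequence, because downstream
classification requires a constant feature dimension.

**Property tables.** The dinucleotide table bundles six standard RNA
helical parameters (rise, roll, shift, slide, tilt, twist); reverse-
complement duplex pairs share values. Tables for K > 2 assign each tuple
the mean of its K−1 constituent dinucleotides' z-scores — the
least-surprising extension when no published K-tuple table exists — and are
re-standardized so every property has mean 0 / variance 1 across the 4^K
tuples. Standardization happens once at table load, which makes δ_j
scale-free (scaling raw properties by c scales δ_j by c² pre-standardization;
a test asserts this homogeneity). Custom tables load from TSV
(`tuple` column + R property columns), so any property system can be
substituted; numeric parity with any particular web service's table choice
is not claimed.

## Classifier

A soft-margin SVM with RBF kernel K(x,y) = exp(−γ‖x−y‖²), solved by
scikit-learn's libsvm binding behind the module contract (the dual
constraints Σα_i y_i = 0, 0 ≤ α_i ≤ C are asserted on the fitted artifact in
tests). Defaults C = 1, γ = 1/#features; the optional grid search evaluates
(γ, C) = (2^a, 2^b), a, b ∈ {−5, −3, −1, 1, 3, 5} (36 pairs) by internal
cross-validated auROC with ties broken toward smaller C then smaller γ.

**Feature standardization.** Features are standardized (zero mean, unit
variance, learned on the training split and stored in the model artifact)
before every SVM fit. Raw PseKNC features live on tiny scales (most entries
≪ 1/4^K), and without standardization γ = 1/#features leaves the RBF kernel
nearly constant: the SVM underfits and leave-one-out estimates invert
through the majority-composition artifact. This mirrors the default
behavior of the widely used R SVM interface this protocol matches.

**Probabilities.** Platt scaling fitted on held-out decision values from an
internal stratified CV of the training set: p = 1/(1+exp(A·f+B)) with
Platt's smoothed targets and the slope A constrained ≤ 0 (L-BFGS-B), so the
probability is monotone in the margin by construction — ranking by
probability always equals ranking by decision value. (A, B) are serialized
with the model. The decision threshold is fixed at 0.5.

**Plug-in learners.** `train(..., learner_factory=...)` accepts any
estimator exposing `fit`/`predict_proba`, evaluated by the same pipeline;
no alternative learners ship with the package.

## Feature selection

SVM-RFE uses a linear kernel (w = Σα_i y_i x_i is only defined there) on
standardized features even though final classification is RBF; elimination
defaults to one feature per iteration (the canonical procedure), with a
configurable step for large feature spaces. w² ties break by original
column order (stable sort) for determinism. The selection curve scores
ranked prefixes (default increment 10, the full set always included) by
k-fold CV auROC with the default RBF SVM, breaking ties toward higher auPRC
and then the smaller subset. By default selection runs on a stratified
random half of the balanced training data (`selection_fraction = 0.5`,
seeded), keeping subset scoring from overfitting the full training set.

## Evaluation

- Stratified k-fold: each class is shuffled (seeded) and split into k
  near-equal parts; fold i unites part i of both classes. Per-fold class
  ratios stay within ±1 example.
- Aggregation: threshold metrics (Sen, Spe, Pre, F) are averaged over
  folds and Acc recomputed as (Sen+Spe)/2; auROC/auPRC are computed on the
  held-out scores pooled across folds. Pooling keeps the curves
  well-defined for LOOCV and stabilizes small folds; a per-fold switch is
  the `fold_metrics` list.
- auROC is the trapezoid area under the threshold-swept ROC curve and is
  tested to equal the pairwise-concordance statistic (ties ½). auPRC uses
  step-wise interpolation (not trapezoid), the standard choice for PR
  curves.
- Balancing undersamples the majority class uniformly without replacement
  (seeded), keeping all minority rows and the original row order.
- Reported percentages round half-even to 2 decimals; raw values are kept
  in the objects and files.

## Synthetic data

The generator draws sequences from a first-order Markov chain over
{A, U, G, C}: row a of the transition matrix blends the class composition
with a same-nucleotide repeat term (stickiness 0.25), giving genuine
dinucleotide structure so the δ_j features carry signal rather than only
the frequency block. Class compositions interpolate between their common
midpoint and the class targets (GC-rich positives 15/35/35/15 vs AU-rich
negatives 35/15/15/35 over A/C/G/U) via `effect` ∈ [0, 1]; `effect = 0`
yields identical class distributions (the null). Mature lengths are uniform
on 20–24 nt, precursors on 80–120 nt, and paired mode embeds each mature
sequence verbatim in its precursor at a random offset.

What the simulator does **not** emulate: hairpin thermodynamics and
base-pairing constraints of real precursors, phylogenetic relatedness
between sequences (real datasets need homology reduction precisely because
of it), composition differences subtler than a global Markov shift, and
class-conditional length effects. Passing tests on synthetic data therefore
demonstrate that the machinery recovers compositional signal when present
and reports chance when absent — not that any particular accuracy will hold
on curated miRNA databases.

## Numerical and design choices

- Redundancy reduction is a greedy, input-order clusterer over global
  alignment identity = matches / alignment columns, with matches maximized
  under free mismatches/gaps (equivalently the LCS), giving the canonical
  column count l_a + l_b − m. It approximates, not reproduces, CD-HIT.
  Positives and negatives are reduced separately by default (jointly via a
  flag).
- Duplicate sequences keep the first occurrence; cleaning is idempotent and
  its two filters commute.
- T→U normalization happens on read, so DNA-alphabet FASTA encodes
  identically to its RNA transcript.
- Combined mode stores mature records and a parallel precursor map keyed by
  the shared id (one flat list would break id uniqueness); encoding
  concatenates the mature vector (`mat_` prefix) with the precursor vector
  (`pre_` prefix).
- The model artifact embeds a format-version string and the encoder
  fingerprint; predicting with a mismatched encoder configuration raises
  rather than silently re-encoding.
- Degenerate inputs: single-class truth yields threshold metrics where
  denominators exist and an explicit error for curve metrics; empty
  post-filter datasets, single-class training sets and non-finite features
  all raise typed errors mapped to CLI exit codes 2/3/4.

## Problem sizes in tests

The suite and the end-to-end checks run at deliberately compact sizes —
encoder oracles on 100 random sequences, planted-signal selection at
n = 200 with 20 informative / 180 noise features, pipeline recovery at
60 sequences per class, null calibration at 100 per class over 20 seeds,
and LOOCV–vs–5-fold agreement at 50 per class — chosen so the full suite
completes in well under a minute while still exercising every stage at
realistic miRNA lengths.

## Known limitations

- The bundled property values are one reasonable published set; feature
  values (not dimensions or invariants) change under a different table.
- Greedy identity clustering can retain pairs CD-HIT would merge and vice
  versa, especially near the threshold.
- Platt calibration on small training sets is coarse; probabilities near
  0.5 should not be over-interpreted.
- LOOCV on balanced data carries the usual majority-composition pessimism
  for weakly separated classes; the 5-fold scheme is the default for a
  reason.
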