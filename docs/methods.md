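# Methods

## Signature and log-signature core

A participant's windowed mood record is treated as a piecewise-linear path
$X:[a,b]\to\mathbb{R}^d$ with $d=5$ channels (four instrument scores plus the
cumulative missing count). The truncated signature is computed exactly via
Chen's identity: the signature of a linear segment with increment $\Delta$ is
the tensor exponential $\sum_k \Delta^{\otimes k}/k!$, and segment signatures
are combined with the truncated tensor product. The log-signature is the
truncated tensor logarithm $\log(1+x)=\sum_n(-1)^{n+1}x^{\otimes n}/n$, which
terminates at level $p$ because $x$ has no scalar part.

Lyndon coordinates are recovered level by level: the expanded standard
bracketing of a Lyndon word $w$ equals $w$ plus lexicographically greater
words, so restricting the Lie element to Lyndon-word tensor coefficients gives
a unitriangular linear system, solved directly. This route (full tensor
logarithm, then a triangular change of basis) was chosen over free-Lie-algebra
arithmetic for simplicity at the small truncation level used ($p=3$; the basis
has $5+10+40=55$ words for $d=5$ by the Witt formula). Basis order is
(length, lexicographic), so the five level-1 coordinates — the per-channel
total increments — come first, which keeps importance reports stable and
interpretable.

A brute-force oracle evaluates individual iterated integrals from the
definition by nested quadrature on a uniform grid refined so that segment
endpoints are grid points (removing bias at kinks). The inner running
integral is integrated against channel increments with trapezoid evaluation:
a pure left-endpoint rule converges only first-order and its bias at level 3
on rough paths is of the same magnitude as the 1e-3 verification tolerance at
the grid sizes used, whereas the trapezoid rule is second-order (and exact at
level 2 for piecewise-linear paths). The oracle shares no code with the Chen
route and is used only in tests.

Numerical tolerances: algebraic identities (Chen, shuffle, subdivision
invariance, exp∘log) are asserted at 1e-10 absolute, appropriate for $p\le 3$
and bounded inputs; oracle comparisons at 1e-3. A degenerate path of
identical points yields the identity signature / zero log-signature rather
than an error: windows with constant accumulated score are legitimate inputs.

## Missingness encoding

Missing entries (sentinel −1) are feed-forward filled with the most recent
prior valid value in the same channel; a *leading* gap, which has no past, is
back-filled from the first subsequent valid value — this mirrors the
feed-forward rationale (no spurious increment at the first observation). The
cumulative count aggregates misses across all four instruments into one extra
channel by default (per-channel counting is available behind a flag but
unused downstream). A channel that is missing for the participant's entire
record has no value to fill from and raises an error naming the participant
and channel.

## Normalisation and windows

Scores are divided by instrument maxima — QIDS 27, GAD-7 21, EQ-5D 100, and
ASRM 20 (the instrument's five items score 0–4 each; the value is
configurable) — and the miss-count increments by $C\times\text{width}=40$,
the maximum total a ten-week window can accumulate, so every channel entering
the signature is scale-free. Channels are then accumulated (cumulative sum
with an origin basepoint). No time channel or other augmentation is added:
the weekly grid is uniform, so reparameterisation invariance of the signature
makes an explicit time channel redundant at this truncation level.

Encoding happens on the full stream *before* windowing (count context crosses
window boundaries); each ten-week window is then re-based to start at the
origin so windows are translation-comparable. Windows slide with stride 1,
giving $W-9$ windows per participant.

## Classification and evaluation

Window features feed a random forest (500 trees, unlimited depth, square-root
feature subsampling, fixed seed; all exposed in `RFConfig`). Cross-validation
is stratified at the *participant* level (k=3 default): all windows of a
participant share one fold, and the train/test participant intersection is
asserted empty on every fold. Window labels equal the participant's
diagnosis.

Participant predictions: hard voting takes the modal window label, with exact
ties falling back to the soft vote (uses available probability information
instead of an arbitrary choice); soft voting takes the argmax of summed
window probabilities, with exact ties resolved to the lowest class index in
the fixed order (BD, HC, BPD) used everywhere (probability vectors, confusion
matrices, triangle vertices). Metrics: accuracy, per-class F1 under both
votings, 3×3 confusion matrices, one-vs-rest ROC/AUC on the soft-vote
probabilities with a percentile bootstrap over participants (B=1000 default)
for the 95% interval. Feature importances are averaged across fold models and
normalised to sum to one; length-1 words are reported as "Incremental effects
of ⟨channel⟩", longer words as interactions, with channel 5 named "the
missing signal".

## Baselines

* **Naive**: per-channel mean over valid in-window scores; an all-missing
  window channel falls back to the participant's full-stream mean.
* **KNN**: missing-aware Euclidean distances between weekly observation rows;
  each hole filled by the mean of its K=5 nearest rows observing that
  variable (scikit-learn's `KNNImputer` provides exactly this behaviour).
* **PPCA**: probabilistic PCA ($x=Wz+\mu+\varepsilon$, isotropic noise,
  $q=2$ components) fit by expectation–conditional-maximisation with missing
  coordinates treated as latent; the observed-data log-likelihood is tracked
  and is non-decreasing by construction. Imputation is the posterior mean of
  the missing coordinates; observed entries are never altered.
* **External**: a pre-imputed sentinel-free cohort CSV can be supplied, which
  is how multiple-imputation pipelines maintained elsewhere plug into the
  harness.

Imputers are fit within each training fold and applied to the held-out rows
(no transductive leakage); a `--transductive` switch reproduces the
impute-once-globally variant. All baselines reuse the MRLSF fold assignment,
classifier configuration and voting, so comparisons are paired.

## Synthetic cohort generator

The generator defines the study conditions for all end-to-end tests. Latent
per-instrument trajectories are mean-reverting AR(1) processes around group
baselines — the simplest process exhibiting the qualitative contrasts of
interest: stability for HC, high innovation variance for BPD, and for BD a
semi-Markov episode overlay (weekly start hazard 0.06, geometric mean
duration 5 weeks, manic episodes shifting ASRM up, depressive episodes
shifting QIDS/GAD-7 up and EQ-5D down). Scores are clipped to instrument
ranges and rounded to integers. Weekly responses go missing independently
with group base rates HC 0.05 < BD 0.25 < BPD 0.40 (per-instrument by
default; whole-week and MNAR — logistic modulation by standardised latent
distress — are available). The default preset uses 52 weeks and group sizes
(53, 52, 34); end-to-end tests use 30 per group.

What the generator does **not** emulate: item-level questionnaire structure,
enrolment/dropout dynamics, calendar effects, diagnosis mixtures or label
noise, and any fitted correspondence to real cohort statistics. Passing tests
therefore demonstrate that the pipeline recovers group structure *when the
generating process contains it*, not a claim about expected accuracy on real
clinical data, whose headline numbers are not reproducible without the
original cohort.

One property worth stating: in the missingness-only configuration (identical
score dynamics in all groups) the naive and imputation baselines still exceed
chance, because the sampling variance of window means depends on how many
valid observations they average — the missingness mask leaks into any
mask-dependent feature. The meaningful comparison, asserted in the acceptance
suite, is the large margin (≥ 0.15, measured ≈ 0.35) by which the
log-signature model with the explicit missing-count channel beats the naive
model under those conditions.

## Problem sizes

Default test and acceptance runs use 30 participants per group × 52 weeks
(3870 windows), five seeds for stochastic checks, and a 30-participant ×
30-week cohort with 20 label shuffles for the permutation null; these sizes
give stable means while keeping full runs to a few minutes.

## Known limitations

Truncation is fixed at $p\le 6$ by the dense tensor representation (fine for
the $p=3$ default; the tensor algebra is dense and $d^p$ grows quickly).
Windows shorter than ten weeks are discarded rather than padded. The PPCA
imputer assumes a single global linear factor structure across all weekly
rows; it is a comparison baseline, not a recommended imputer. Multiple
imputation (MICE-style) is intentionally not implemented — externally imputed
cohorts enter through the `external` path.
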