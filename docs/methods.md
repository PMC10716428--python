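# Methods

This note documents the models, procedures, and design choices behind
`ckdprog`, and what its synthetic experiments do and do not demonstrate.

## Problem and outcome definition

The prediction target is progression of chronic kidney disease from stages
II/III (eGFR 30–89 mL/min/1.73 m²) to stages IV/V (eGFR ≤ 29) within a
prediction window of `t_pre` days.  Because single eGFR readings are noisy
and transient dips are clinically distinct from sustained decline, both
study entry and the outcome are defined through *stable periods*: two
in-band readings at least 90 days apart with every intermediate reading
also in band.  Internally a stable period is detected as a maximal run of
consecutive in-band readings whose time span reaches 90 days; this is
equivalent to the anchor-pair definition (any qualifying pair lies inside
an in-band run, and the endpoints of a ≥ 90-day run form a qualifying
pair), and the equivalence is verified against a brute-force pairwise
oracle in the test suite.  Band bounds are inclusive: a reading of exactly
29 belongs to the IV/V band, 89 to stage II.

A patient is *eligible* with ≥ 1 stable stage II/III period and ≥ 4 eGFR
readings.  A *case* additionally has ≥ 1 stable stage IV/V period whose
first reading time is the transition point T_tra; the first two readings
must not lie inside any stable IV/V period (patients already late-stage at
record start carry no usable early-stage history).  A *control* has no
stable IV/V period.  Eligibility is checked in a fixed order
(too-few-readings, then no-stable-early-period, then
first-readings-in-late-period) so exclusion reasons are deterministic.

## Time-series assembly

Observations are binned into half-open `t_w`-day intervals anchored at each
patient's first observation; interval *n* is stamped with its midpoint
T_n = (n − 1 + 0.5)·t_w.  Within an interval, lab and vital readings are
arithmetically averaged, behavior codes take the latest reading,
demographics are constant columns, and T_n itself is appended as the time
feature.  Empty intervals between observed ones are kept as missing rows so
the time step stays uniform.  Defaults: t_w = t_gap = 7 days,
t_pre = 365 days (90/1095/1825 supported), maximum length 100 points
(latest kept), minimum usable length 5.

Case series are cut at T_tra − t_gap; the gap period prevents the label
from leaking through measurements taken essentially at the transition.  A
case is valid only if the transition falls inside the prediction window
measured from the last used point: t_gap ≤ T_tra − T_last ≤ t_pre.  Control
series lose their final t_pre span, so the retained history is known
progression-free for t_pre days.  The harder stage II/IIIa task is built by
truncating each patient's entire observation stream at the first eGFR ≤ 44
(start of stage-IIIb-or-worse information) and re-deriving status on the
truncated stream; with the synthetic generator's gradual trajectories this
removes almost all cases, which is the expected direction of the effect
(the alternative reading — dropping only IIIb-period rows — would leave a
gap in the series and is not implemented).

Missing cells are imputed per variable by last-observation-carried-forward,
then next-observation-carried-backward, then the training-fold median; the
pre-imputation mask is preserved for audit.  Continuous features are
z-scored with training-fold moments.  Both steps run inside the
cross-validation loop so no fold statistics leak into test data.

## Matching

Each case is matched without replacement with up to four controls agreeing
exactly on race, sex, and sequence length, with age (age at record start
plus T_last/365.25 years) within a 5-year tolerance, nearest ages first.
The default algorithm is greedy in a seeded random case order; input row
order does not affect the result because pools are canonically sorted
before the shuffle.  An optimal variant (maximum-cardinality bipartite
b-matching via min-cost max-flow, age gaps as costs) is available as
`MatchSpec(method="optimal")` and doubles as the oracle in tests.  Cases
with no eligible control are retained and flagged — dropping them would
bias the dataset toward strata rich in controls.  When every case reaches
the full ratio, the matched controls reproduce the case sequence-length
distribution exactly.

## Models

**LSTM classifier.**  A single masked LSTM layer reads the padded sequence
of feature vectors; the final hidden state feeds a stack of dense ReLU
layers with dropout and a two-node softmax.  Training minimizes weighted
cross-entropy — control weight 1, case weight equal to the control/case
count ratio of the training split — with Adam (learning rate 1e-3, batch
64), early stopping on validation loss (patience-limited, best weights
restored), and a plateau schedule that halves the learning rate and
restarts from the best weights when validation loss stalls.  The dropout
rate, shared by all dense layers, is the only tuned hyper-parameter,
selected from the grid {0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7} by validation
loss.  Architecture presets: 64 LSTM units with dense (64, 32, 16) for the
all-variables input, 32 units with dense (16,) for the essential set; exact
node counts are configuration, not contract.  The network is implemented
directly in numpy with explicit backpropagation through time (validated
against finite differences in the test suite); the model is small enough
that this is fast on one CPU.  Setting the grid to {0} with a large
patience reduces training to plain weighted cross-entropy, an ablation
hook.

**Cox baselines.**  Both regress time-to-progression via the partial
likelihood (lifelines, penalizer 0.01 for numerical stability; constant
columns dropped).  Cases contribute an event at T_tra − T_1; controls are
censored at T_last + t_pre − T_1, the end of the span they are known
progression-free.  The static model uses covariates at the first time
point.  The dynamic model uses counting-process rows (start, stop,
covariates, event), one per grid point, contiguous and lossless.  The time
feature is excluded from Cox covariates — time enters through the hazard
axis.  Risk scores are 1 − S(window | x); the dynamic model evaluates the
baseline-hazard increment over each patient's own window
(T_last, T_last + t_pre] at the last observed covariates, the natural
conditional-risk reading of a model whose hazard follows current covariate
values.

**Snapshot baselines.**  Random forest (scikit-learn, 300 trees) and
LightGBM are trained on each patient's latest feature vector.  The random
forest merges training and validation folds (nothing to tune); LightGBM
uses the validation fold to stop boosting rounds.

## Evaluation

Each cross-validation trial draws one stratified random partition into ten
folds and assigns eight to training, one to validation, one to testing
(rotation through all ten test folds is not performed; one random
assignment per trial keeps many trials affordable and every trial
independent).  Matched case-control sets stay within a single fold by
default so near-identical twins never straddle the train/test boundary.
Metrics: AUROC (midrank ties), AUPRC (step-wise average precision), and
MCC at a 0.5 cutoff (0 returned for degenerate tables).  Race-stratified
AUROC is computed per test fold where both classes are present; the
summary reports per-race means/sds and the maximum pairwise difference of
means.  A test fold missing a class triggers one resample, then an error.
All seeds derive from the plan seed.

## Forward variable selection

Selection starts from the time feature alone (always included).  Within
each trial — its own fold partition, reused across candidates so
comparisons are paired — every unselected variable is tried and the one
maximizing test-fold AUROC is added.  Trials may choose different
variables, so each step reports selection frequencies across trials and
the modal choice.  Step-wise AUROC distributions are compared with the
all-variables model on the same partitions by two-sided paired t-tests
(p = 1 with a flag for zero-variance differences), Benjamini–Hochberg
adjusted across steps.  The search costs O(D²) model fits per trial;
experiments here use one step (the most predictive single variable), which
is the part of the path that identifies eGFR.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes, not
any real cohort.  Per patient: visits at 1 + Gamma(shape 2) day gaps (mean
30 days); a linear eGFR trajectory baseline + slope·t/365 with Gaussian
measurement noise (sd 5), baseline U(50, 80) so everyone starts in stages
II/III (the first reading is clipped into [30, 89], mirroring study entry),
floor at 5.  Progressors (default fraction 0.15) draw slopes from
N(−10, 3) clipped to [−20, −4] per year, and their follow-up extends
200–500 days past the expected crossing of eGFR 29 so the late-stage
stable period is constructible; non-progressors draw from N(−1, 1) clipped
to [−2, 1] with follow-up U(540, 2190) days.  Serum creatinine is
70/eGFR + noise (inversely monotone in the underlying trajectory); other
labs/vitals are stationary patient-level offsets plus visit noise around
clinically plausible levels; behaviors are two-state Markov chains with
persistence 0.9 and realistic prevalences; every non-demographic
observation is dropped MCAR at rate 0.3 (each patient's first eGFR reading
is kept).  `covariate_signal=False` decouples creatinine from eGFR,
confining all predictive signal to the eGFR series itself — the condition
used by the selection-recovery experiment.  Identical configuration and
seed reproduce the tables byte-identically.

What the generator does *not* emulate: informative missingness, visit
frequency that responds to disease severity, acute kidney injury episodes,
nonlinear or change-point trajectories (a config flag reserves the
extension), medication effects, and coding noise.  Passing tests therefore
demonstrate that the pipeline and models behave correctly under the stated
assumptions, not that the reported accuracy transfers to clinical data.

## Reference experiment sizes

The reference synthetic experiment uses 2,000 patients (≈ 220 valid cases,
≈ 1,065 matched samples), five cross-validation trials, and the eGFR-only
feature set with the essential-variant LSTM and a restricted dropout grid
{0, 0.1, 0.2}; the selection-recovery experiment uses 500 patients, ten
trials, and one selection step; the label-permutation null runs on the
full matched dataset, where five-trial mean AUROC is estimated tightly
enough to be compared with chance.  These sizes are the package's
standing study conditions for its own experiments and are what
`scripts/acceptance.py` re-runs.

## Known limitations

* The dynamic Cox prediction uses last-known covariates over the patient's
  future window; other conventions (covariate path extrapolation) exist.
* Greedy matching is order-dependent in adversarial pools; the optimal
  flag exists but is quadratic in pool size.
* The LSTM trains full-batch-sequential on CPU; very long sequences or
  wide inputs would need minibatch truncation or a compiled backend.
* Stage-IIIb exclusion truncates all subsequent history; with gradual
  synthetic trajectories this leaves very few cases, so the harder task is
  exercised structurally rather than at scale.
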