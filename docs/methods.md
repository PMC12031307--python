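# Methods

## Scientific setting

Storage temperature strongly affects citrus freshness, but mandarins show
little visible change over a few days of warm storage. Bioelectrical
impedance spectroscopy (BIS) probes the tissue non-destructively: an AC
sweep (here 30 log-spaced points, 50 Hz–1 MHz) yields a complex impedance
Z(ω) = Z' + jZ'' per fruit, usually reported as magnitude |Z| and phase θ =
arctan(Z''/Z')·180/π. Intra- and extracellular fluids behave resistively;
the cell membrane behaves as an imperfect capacitor. Water loss at room
temperature concentrates the apoplast and shrinks membrane area, so the
spectrum drifts over days of warm storage while cold-stored fruit barely
change. `bisfruit` implements the full analysis chain for this design —
forward circuit model, circuit fitting, cohort simulation, feature
engineering, and a multi-classifier benchmark — so that every stage is
testable without access to a measured cohort.

## Equivalent-circuit forward model

The circuit is a modified Hayden network with constant-phase elements
(CPE). A CPE generalizes the capacitor:

    Z_CPE(ω) = 1 / (Q·(jω)^α),   (jω)^α = ω^α·(cos(απ/2) + j·sin(απ/2)),

with Q > 0 (units s^α/Ω) and ideality factor α ∈ [0, 1]; α = 1 is an ideal
capacitor, α = 0 a resistor 1/Q. A lone CPE has phase exactly −α·90° at
every frequency. The total impedance is

    Z(ω) = [R_e ∥ Z_CPE_e(ω)] + [R_ex ∥ (R_i + Z_CPE_m(ω))],

electrode block in series with the tissue block, a ∥ b = ab/(a+b): R_e is
the electrode contact resistance, CPE_e its non-ideal capacitive behavior,
R_ex/R_i the extra-/intracellular resistances and CPE_m the membrane
element — five elements, seven scalar parameters. An alternative
series-electrode wiring (R_e + Z_CPE_e + tissue) is available behind the
`topology` switch; the parallel wiring is the default because a bare
contact resistance with a parallel double-layer element is the standard
lumped electrode-interface model. For ideal CPEs the limits are
Z(ω→0) → R_e + R_ex and Z(ω→∞) → R_ex∥R_i.

### Exchange degeneracy and canonical labeling

Writing each parallel block as a constant minus a relaxation term shows
that

    Z = (R_e + R_ex) − R_e²/(R_e + Z_e) − R_ex²/((R_ex + R_i) + Z_m)

and the two relaxation terms can be exchanged between the blocks by an
explicit algebraic map (`ec_fit.exchange_equivalent`), giving a second
parameter set whose impedance is *identical at every frequency*. The model
is therefore globally identifiable only up to this two-fold relabeling; in
development roughly a third of noiseless fits converged to the swapped
branch with machine-zero residuals. All fits are therefore canonicalized:
of the two equivalent decompositions the package reports the one in which
the electrode block carries the smaller resistance (contact resistance is
small against the extracellular resistance of intact tissue). The
relabeling is exact, so fit quality is untouched. Parameter-recovery
statements in the tests are statements about the canonical labeling.

## Circuit fitting

Fits minimize a modulus-weighted, per-point-normalized chi-square over the
real and imaginary residuals,

    χ² = (1/2N) Σ_k [ ((Z'_meas,k − Z'_mod,k)/|Z_meas,k|)²
                    + ((Z''_meas,k − Z''_mod,k)/|Z_meas,k|)² ],

the standard weighting in impedance practice: magnitudes span orders of
magnitude across the sweep, and without the 1/|Z| weight the low-frequency
points would dominate. The 1/(2N) normalization makes the statistic
comparable across grid lengths. A fit with χ² ≤ 3×10⁻⁴ is treated as
accurate (the `quality_gate`); with the generator's default measurement
noise (0.5% on |Z|, 0.5° on phase) typical fits land near 4×10⁻⁵.

Minimization uses `scipy.optimize.least_squares` (trust-region reflective)
with an analytic Jacobian. Resistances and CPE magnitudes are optimized in
log-space (enforcing positivity and equalizing scales); ideality factors
are box-bounded to the closed interval [0, 1] directly — a logit transform
cannot represent the endpoints. Log-coordinates are additionally bounded to
±46 (≈10^±20), far outside any physical value, purely to prevent floating
point under/overflow. Tolerances: xtol = ftol = 1e−10, at most 2000
residual evaluations per start.

Because circuit fits are sensitive to their starting point, each spectrum
is fitted from 12 deterministic starts: one heuristic start read off the
spectrum (low-frequency |Z| ≈ R_e + R_ex split 15/85, high-frequency |Z| ≈
R_ex∥R_i, membrane Q from the frequency of the phase minimum, α = 0.8) plus
11 log-uniformly jittered copies drawn from a fixed seed. The lowest-χ²
converged start wins; ties break on start index, so the result is
independent of start order. Twelve starts were chosen because smaller
schedules occasionally left one of fifty random noiseless draws in a
χ² ≈ 5×10⁻⁶ local optimum; with twelve, all fifty recover within 1%.

## Synthetic cohort generator

The generator emulates a two-temperature storage study: 46 fruit per
(size × storage) cell — 184 fruit, 552 spectra over days 0/1/2 — with
storage labels assigned by seeded permutation *after* drawing, so day-0
distributions are exchangeable between groups. It aims to reproduce the
qualitative structure of such experiments, not any particular fruit:

* **Diameters**: small 55 ± 3 mm, large 70 ± 3 mm (nominal market sizes;
  placeholders, clearly bimodal when pooled).
* **Baseline circuit parameters**: log-normal between-fruit variation
  around medians R_e = 500 Ω, Q_e = 2×10⁻⁶, R_ex = 20 kΩ, R_i = 6 kΩ,
  Q_m = 8×10⁻⁷ (log-sd 0.2–0.3); α_e = 0.85, α_m = 0.80 (sd 0.03,
  clipped). These put |Z| in the 10–20 kΩ range with the membrane
  relaxation at the low edge of the sweep — kΩ-scale fruit impedances with
  a low-frequency dispersion are typical of surface-electrode fruit
  measurements.
* **Size coupling**: membrane capacitance scales with membrane area, so
  Q_m ∝ (d/62.5 mm)². With the relaxation at the band edge this makes
  larger fruit show *smaller* low-frequency |θ| — the coupling direction is
  a config knob (`qm_diameter_exponent`) because the sign convention of
  published phase plots is ambiguous.
* **Storage drift** acts multiplicatively on the latent parameters, never
  on spectra, so every spectrum stays a physically consistent circuit
  response. Room per-day median factors: R_ex ×1.16, R_i ×1.09, Q_m ×0.85
  (water loss: concentrated apoplast, shrinking membrane area), with
  per-fruit log-normal jitter (sd 0.10) and a surface-to-volume size
  effect — the per-day log-drift is scaled by (62.5/d)³, smaller fruit
  drying faster. Cold factors are log-normal around 1 (sd 0.05). Drift
  compounds across days. With jitter 0 the cold group is exactly static.
* **Measurement noise**: multiplicative 0.5% on |Z| and additive 0.5° on
  phase, applied in polar form.

Drift magnitudes were fixed so that a tuned classifier on raw day-1/2
spectra reaches roughly 0.7 CV accuracy — hard but not hopeless, the
regime in which baseline-correction actually matters — while delta
features reach ~0.92–0.95 and the raw ≤ changes ≤ changes+diameter
ordering holds across seeds. They live in `CohortParameters`, not in code.

What the generator does **not** emulate: purchase-batch effects (a
two-batch offset exists but defaults to off), humidity and re-warming
protocols (they motivate but do not parameterize the drift rules),
mechanistic water transport or respiration, chilling injury, electrode
placement variability, or drying hydrogel electrodes. Passing tests
therefore demonstrate the correctness and calibration of the pipeline on
data with this structure, not performance on any real cohort.

## Feature engineering

Six dataset variants are assembled from a cohort (days 1 and 2 only —
day 0 is consumed as the per-fruit baseline and never emitted as an
instance): raw |Z|+θ spectra (60 features), their day-0 deltas
ΔX_t = X_t − X_0 (60), deltas plus diameter (61); and the same three with
the seven fitted circuit parameters (7/7/8). Feature order is fixed:
magnitudes by ascending frequency, then phases; circuit parameters in the
order r_e, q_e, α_e, r_ex, r_i, q_m, α_m; diameter last. Deltas are
computed on raw values *before* any normalization — this is the only order
that keeps a drift-free group's deltas centered at zero — with a flag for
the reverse order. Diameter is a day-0 constant per fruit.

Standardization is per-feature z-scoring with population sd (ddof = 0,
configurable); zero-variance features are centered only and flagged. The
default pipeline fits scaling statistics inside each training fold
(leak-free); a `paper_mode` flag instead normalizes the pooled data before
splitting, reproducing the common but leaky practice of normalizing
everything at once. The train/test split is stratified 8:2 with the train
size rounded half-up (368 → 294/74).

## Classifier benchmark

Eight scikit-learn families are compared: SVM, logistic regression (LR),
multi-layer perceptron (MLP), k-nearest neighbors (kNN), random forest
(RF), linear discriminant analysis (LDA), Gaussian naive Bayes (NB) and
decision tree (DT). Hyperparameters are tuned by exhaustive grid search
under 5×-repeated stratified 10-fold CV on the training split only; the
winning grid point's 50 fold accuracies are retained. Default grids: SVM
C ∈ {0.1, 1, 10, 100} × {linear, RBF(γ ∈ {scale, 0.01, 0.001})}; LR
C ∈ {0.01, 0.1, 1, 10}; MLP one hidden layer ∈ {16, 32, 64}, L2 ∈ {1e−4,
1e−3}; kNN k ∈ {3, 5, 7, 9, 11}; RF trees ∈ {100, 300} × depth ∈ {none, 5,
10}; DT depth ∈ {none, 3, 5, 10}; LDA and NB have no grid. All grids are
configurable. SVC carries a deterministic `max_iter = 20000` cap so
large-C linear fits on overlapping classes cannot dominate the runtime;
truncated fits surface as ConvergenceWarnings and essentially never win
the grid.

The fold assignment is seeded and *shared* across every grid point, model
and dataset (asserted by a SHA-256 hash of the test-index sequence), so
two models' 50 accuracy estimates are paired fold-by-fold. Dataset
variants are compared per model with the two-sided Wilcoxon signed-rank
test on those paired differences. Zero differences are discarded
(Wilcoxon's original convention; all-zero input returns p = 1). With ≤ 25
nonzero differences the exact tail is computed by dynamic programming over
doubled midranks — exact even under ties — otherwise scipy's normal
approximation with continuity correction is used. Within each dataset
family (bioimpedance-based, circuit-parameter-based) compact letters are
assigned at p < 0.05: variants sharing no significant difference share a
letter; intransitive patterns produce overlapping letters ("ab") rather
than an artificial separation. No multiple-testing correction is applied
across the three pairwise comparisons by default (a Holm option exists).

Held-out evaluation refits the winning configuration on the full training
split and predicts the test split once. Confusion-matrix metrics use the
room-storage group as the positive class (accuracy, precision, recall,
F1 = harmonic mean of precision and recall), with per-class values
available by swapping the positive class. A PCA projection utility
supports visualization of raw-versus-delta separability.

## Reproducibility and problem sizes

All randomness descends from one master seed through named
`numpy.random.SeedSequence` children (cohort, fit, split, CV), so a run is
reproducible from its manifest. The test suite and the acceptance script
run the cohort at its design size (184 fruit, 552 spectra). The
dataset-ordering property is checked over 20 seeded cohorts with the tuned
SVM; parameter recovery over 50 random draws; the χ² gate over 100 noisy
replicates — sizes chosen to make the binomial/recovery statements sharp
while keeping a full run in the minutes range on one core.

## Known limitations

* The χ² gate value is meaningful only under this package's χ²
  definition; other normalizations rescale it.
* The exchange degeneracy means circuit parameters from other software may
  correspond to the swapped branch; compare after canonicalization.
* The generator's drift is phenomenological (multiplicative factors), not
  mechanistic; absolute accuracies on synthetic cohorts say nothing about
  accuracies on real fruit, only orderings and pipeline correctness do.
* With α fixed at 1 the reduced 5-parameter fit is supported
  (`fix_ideal_alpha`), but mixed configurations (one α free) are not.
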