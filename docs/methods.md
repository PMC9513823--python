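# Methods

This note documents the models and estimators implemented in `qeegml`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical decisions that were genuinely open.

## Synthetic cohort generator

Each subject is a 19-channel (ten-twenty montage), 250 Hz, 5-minute (default;
4-minute minimum) recording built from three controllable ingredients, so
every downstream feature has an analyzable ground truth:

1. **Band-limited Gaussian noise** per channel, one component per frequency
   band (δ, θ, α, µ, β, γ), with variances set to the class profile's target
   relative band powers. Components are synthesized spectrally: complex
   Gaussian spectra shaped by raised-cosine band masks whose transitions lie
   inside the band (0.5 Hz, shrunk for narrow bands). This is equivalent in
   distribution to ideally filtered white noise and keeps the measured
   relative powers on target; it replaced time-domain FIR filtering of white
   noise purely for runtime (an order of magnitude on whole-cohort
   generation), not behavior. The remainder of the unit power budget is
   broadband 1–100 Hz background.
2. **Shared latent sources** per band and channel group, mixed into member
   channels with gain √a where `a = 0.5 × coherence_scale`. Two channels
   carrying shared-power fraction `a` have magnitude-squared coherence
   ≈ a² in that band. Channel gains are balanced ±1 signs (shuffled): the
   sign does not affect coherence, but a sign-balanced source survives
   average re-referencing, whereas a common-mode source would be subtracted
   away with the channel mean.
3. **Phase–amplitude coupling**: the γ component is multiplied by
   (1 + d·cos φ_α)/√(1 + d²/2), where φ_α is the channel's α-band
   instantaneous phase and `d = pac_depth`. Only the α→γ pairing is
   injected; θ→γ and θ→α remain at the estimator's bias floor. The measured
   modulation index is attenuated relative to d²/(4 ln 18) because (a) the
   1–100 Hz background dilutes the γ envelope and (b) re-filtering to
   [25, 40) Hz clips modulation sidebands that fall outside the band; both
   effects are physical properties of the measurement, and the injected
   depths (0.30/0.22/0.15 for normal/TBI/stroke) keep the class ordering
   measurable above the floor.

Artifacts are Poisson event trains: ocular events are ~0.4 s Gaussian-bump
transients (spectral mass < 4 Hz) with a frontal-dominant spatial pattern
(FP1/FP2 gain 1, neighbors 0.3–0.5), ~120 µV; muscle events are 0.3 s
bursts of 20–100 Hz noise with a temporal-dominant pattern, ~35 µV SD. The
event log suffices to reconstruct the injected signal exactly, which is what
the oracle IC labeler uses.

Class profiles default to the documented injury signatures: TBI raises
relative δ (0.24→0.30), lowers α (0.30→0.25) and µ (0.10→0.08), and reduces
the global coherence multiplier (1.0→0.75); stroke applies the same
directions at twice the magnitude plus a θ increase (0.16→0.20). The θ sign
is configurable because reports on its direction conflict; the default
follows the topographic and discussion-level accounts (increase). Effect
magnitudes are config-exposed (`ClassProfile`), and per-subject lognormal
jitter (σ = 0.05) provides between-subject variability. Demographics follow
the observed training-cohort composition: sex ratios 29/47/3 (normal),
74/20/4 (TBI), 62/47/6 (stroke) with an explicit "unknown" category; ages
N(47.6, 18.7²), N(42.7, 16.7²), N(59.7, 9.7²) truncated to [1, 85];
medication counts Poisson with means 1.4/1.4/1.5. Default cohort sizes are
79/98/115 training and 26/44/50 independent-validation subjects.

**What the generator does not emulate:** dipolar source geometry and volume
conduction (channel covariance has no spatial falloff), non-stationarity,
1/f spectral slope (band plateaus instead), realistic artifact morphology,
or any pathophysiology. Passing tests therefore demonstrate that the
*pipeline machinery* recovers planted class structure — not that the
clinical effect sizes or accuracies would be reproduced on real EEG. With
the default effect sizes the synthetic classes are nearly separable; the
recovery tests check ordering relations (above ZeroR, above the
normal-vs-abnormal ceiling, separated from the permutation null), not
accuracy values.

## Preprocessing

The analysis segment is fixed: samples from t = 60 s to t = 240 s
(3 minutes, first minute excluded); shorter recordings are rejected. The
1–100 Hz bandpass is a Hamming windowed-sinc FIR with transition widths of
25 % of the lower edge (0.25 Hz) and min(25 %, 5 Hz) at the upper edge,
−6 dB points mid-transition. Because a symmetric odd-length FIR applied
with centred convolution is exactly zero-phase, the filter is applied once
via FFT convolution with reflection padding (verified: < 1 dB ripple over
2–95 Hz, > 20 dB attenuation at 0.25 and 115 Hz, filtering commutes with
time reversal). Resampling is polyphase with anti-aliasing. Average
re-referencing subtracts the instantaneous channel mean; it is idempotent
and never drops channels (the feature schema requires all 19 everywhere).

ICA uses fixed-point negentropy ICA (scikit-learn FastICA) on the
per-subject 3-minute segment, with components capped at the numerical rank
(18 after average reference). Component labeling is pluggable:

- **oracle labeler** (synthetic data): a component is labeled "eye" or
  "muscle" when the projection of the known injected artifact signal
  explains > 30 % of its variance;
- **heuristic labeler** (no ground truth): narrowband 50/60 Hz → line
  noise; > 50 % of power below 4 Hz with frontal-dominant mixing weights →
  eye; > 50 % above 20 Hz with temporal-dominant weights → muscle; otherwise
  brain. It is a transparent stand-in for trained component classifiers and
  only flags well-isolated components.

On this generator's signals the sources are near-Gaussian, so FastICA's
rotation frequently fails to converge (a Gaussian subspace has no
identifiable rotation). After bounded seed retries the final decomposition
is used and flagged `converged=False` in the `ICReport`: the
mixing/unmixing factorization — hence reconstruction and variance-based
labeling — is unaffected by the undetermined rotation, and raising instead
would make the clean variant unusable on exactly the data the generator
produces. Hard numerical failures still raise.

## Feature estimators

- **Welch PSD**: 2-s Hamming segments, 50 % overlap, density scaling
  (Parseval-consistent). Band powers integrate over half-open [lo, hi)
  intervals so adjacent bands never share a bin; the printed 20–25 Hz gap
  between β and γ is preserved, not bridged. Relative power divides by the
  closed 1–100 Hz total; a zero-power channel raises instead of emitting
  NaN. Whole-segment spectra are used (not epoch averages).
- **Coherence**: magnitude-squared coherence from 30-s non-overlapping
  Hamming epochs (6 per segment), computed for all 171 pairs at once from
  one epoch-FFT array and cross-checked against `scipy.signal.coherence`.
  Per-band values are unweighted means over in-band bins. The estimator has
  a bias floor of ≈ 1/K for K epochs at zero true coherence; tests account
  for it explicitly. Broadband (1–40 Hz) coherence for the contrast maps is
  computed directly on that interval, since the six bands do not tile it.
- **Spectral entropy**: Shannon entropy in bits of the normalized spectrum
  over the 1–100 Hz bins (the filter passband). The bin-count reading of
  the normalizing domain is adopted; zero bins contribute nothing, so
  H ∈ [0, log₂ N_bins].
- **PAC modulation index**: instantaneous phase of the lower band and
  amplitude envelope of the upper band from the analytic signal, 18 phase
  bins on [−180°, 180°), MI = D_KL(P, U)/ln 18 ∈ [0, 1] (natural log in
  both numerator and normalizer so the degenerate distribution gives exactly
  1). The lower band supplies phase — the convention of the method the MI
  definition comes from. PAC is computed on the full 180-s segment.

Assembly enforces the census (1330, or 1333 with demographics), canonical
ordering, and finiteness. Sex is encoded 0/1/2 (M/F/unknown) and treated as
categorical: exempt from standardization and PCA rotation, tested by
chi-square contingency in the statistics route.

## Feature selection

- **Statistics**: per-feature one-sample K-S normality check (recorded as a
  diagnostic; the rank-based branch is used regardless, matching the
  protocol's finding that qEEG features are non-normal), Wilcoxon rank-sum
  for two classes or one-way ANOVA for three (post-hoc Tukey recorded, not
  gating), then Benjamini–Hochberg step-up at q = 0.05. `bh_select` is the
  exact largest-k rule and is property-tested against a brute-force scan and
  statsmodels.
- **Regularized LDA**: pooled within-class covariance shrunk toward its
  diagonal, S(γ) = (1−γ)S + γ diag S, discriminant direction w solving
  S(γ)w = μ₁−μ₀ via the Woodbury identity (cost scales with subjects, not
  the 1330 features), and coefficient soft-threshold δ. The (γ, δ) pair
  minimizing k-fold CV misclassification over a 50×50 grid is chosen
  (γ linear on [0, 1]; δ log-spaced over 10⁻⁴–10¹ times the median
  coefficient scale — the grid *ranges* are this package's choice, only the
  step count is inherited). Features with |w| below mean + 1 SD of all |w|
  are eliminated; features exactly at the threshold are kept. Multiclass
  uses one-vs-one discriminants and unions the survivors.
- **Sequential selection**: greedy add (forward, from empty) or remove
  (backward, from the LDA survivors) of the single feature minimizing mean
  10-fold CV misclassification of a linear discriminant over Monte-Carlo
  repartitions (default 50), stopping when no move strictly improves; ties
  break to the lowest column index. Forward and backward use independently
  seeded partitions.
- **PCA**: minimal leading components with cumulative explained variance
  ≥ 95 %, categorical sex appended unchanged downstream.

Standardization is always fit on the training split and applied to held-out
tables; zero-variance features get SD 1 (standardized to 0) and are flagged.

## Classifiers and validation

SVMs use box constraint C = 1 (the protocol leaves it unstated) and
polynomial kernels (x·y + 1)^d with unit coefficient; the Gaussian kernel is
exp(−‖x−y‖²/s²) with s ∈ {4√N, √N, √N/4} recomputed from the
post-selection feature count (coarse = 4√N). "Cubic distance" K-NN is
Minkowski order 3; the weighted variant uses squared-inverse-distance
weights; K is capped at the training size with a warning. One-vs-one
decoding is vote counting (equivalent to minimal code distance for OVO
codes) with ties broken toward the lowest class index.

Repeated k-fold CV draws a fresh unstratified uniform partition per
iteration and records the pooled-fold (cumulative) accuracy; the
random-label null permutes labels per iteration before the identical CV.
Distributions are compared by two-sample K-S with a 10⁻¹⁰ significance flag
that additionally requires a higher true-label mean. By default
standardization and selection happen once on the full training table — the
reference protocol, which is optimistic for CV — and a `fold_transform`
hook refits any transform inside every fold for nested (leakage-free)
estimates. Desk-scale default is 200 CV iterations (`--full-iters` switches
to 1000).

Two closed-form baselines anchor every run: ZeroR = max class fraction, and
the normal-vs-abnormal ceiling P(normal) + P(TBI)² + P(stroke)², the best
accuracy of a three-class model that recognizes normal perfectly but
guesses among the abnormal classes in proportion to prevalence. The
three-class counts these are evaluated on are explicit inputs (the source
tables are internally inconsistent about one stroke/TBI count, so no count
is hard-coded). An independent validation is a "success" only when its
accuracy is strictly above the IV ZeroR.

A note on permutation nulls: the null *mean* equals ZeroR exactly only for
learners that collapse to majority-class prediction under permuted labels
(e.g. K-NN with K capped at the training-fold size). Discriminative
learners fit noise and land between the proportional-guessing rate Σ p_c²
and ZeroR; the test suite asserts the exact property for the
majority-collapsing learner and documents the band for the linear SVM.

## Group contrasts

Every subject's features are z-scored against the normal class's mean and
SD (ddof = 1); zero-SD baseline features are flagged and omitted. Per
comparison class, the median z per feature is the group summary (medians,
not means, throughout). Category summaries take the median over features
within absPSD, relPSD-per-band, Coh, SE, PAC (and bbCoh when present).
Coherence pair maps keep pairs with broadband |median z| above 0.5, signed
by direction; topography tables give per-channel median z per band. Any
class can serve as baseline (e.g. stroke-vs-TBI uses TBI).

## Problem sizes used in tests

The test suite exercises the full default cohort spec (79/98/115 + 26/44/50)
only structurally; signal-recovery tests run the complete pipeline on a
cohort with the same class profiles and imbalance at reduced size (train
12/15/18, IV 4/7/8, 240-s recordings) with 50 CV/null iterations — the
package's desk-scale configuration, chosen so the whole suite runs on one
CPU in a few minutes. Accuracy assertions at this scale are ordering
relations, never point values.

## Known limitations

- The heuristic IC labeler detects only well-isolated, strongly expressed
  artifact components; it is not a substitute for a trained classifier and
  the raw-vs-clean comparison on synthetic data mostly reflects the oracle
  labeler.
- EDF output is plain EDF (not EDF+), integer sampling rates and
  whole-second durations only; 16-bit quantization bounds round-trip error.
- Sequential selection is O(features × moves × CV fits) and is impractical
  on the full 1330-feature table at the reference Monte-Carlo settings;
  the pipeline exposes `fsfs_max_moves` and `sfs_mc_reps` to bound it.
- The fidelity-mode leakage (selection before CV) is reproduced on purpose;
  nested mode gives honest generalization estimates and differs noticeably
  on small cohorts.
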