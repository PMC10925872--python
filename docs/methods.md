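# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `cvrasl`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulus protocol and trace generation

The hypercapnic challenge is a fixed block + ramp design: 300 s at the
subject's baseline end-tidal CO2 (PetCO2), a +10 mmHg block for 90 s,
120 s recovery, a linear ramp to +12 mmHg over 180 s, and a 90 s tail —
780 s in total. `generate_petco2_trace` samples this piecewise target on a
uniform grid (default dt = 0.1 s) and adds white noise to emulate
breath-to-breath variability. The ramp reaches exactly baseline +
12 mmHg at its final sample, so the trace maximum is a deterministic
anchor. Baseline PetCO2 defaults to 40 mmHg, a typical physiological
value; patients' individual baselines vary and the parameter is exposed.

## BOLD phantom

Per brain voxel v the forward model is

    S(v, t) = b(v) · [1 + cvr(v)/100 · (P(t − lag(v)) − P0)] + drift·t + ε

with P the PetCO2 trace looked up by nearest grid point, P0 the protocol
baseline, cvr in %BOLD/mmHg (negative inside the steal territory) and lag
a pure temporal shift. Dispersion of the response shape is deliberately
not modeled: the lag-mapping estimator is itself a pure-shift matcher, so
shift-only ground truth makes recovery exactly checkable. Large-vein
voxels receive 10× the nominal noise standard deviation, which places
them beyond the 98th-percentile temporal-noise cut and exercises the
vein-masking stage. The default grid is a small ellipsoidal head phantom
(16×16×10 voxels at 2.292×2.292×2.5 mm) with CSF core, WM interior, GM
shell, a metastasis with an edema collar, a treated (excluded) lesion,
scattered vein voxels, and a spherical steal territory of 12% of the
brain; small grids keep the full cohort × replicate studies at desk
scale, and the sizes used by each study are chosen in the tests/scripts
themselves.

A grid-commensurability caveat: exact (machine-precision) round trips
between generator and estimator require the BOLD frame times and the lag
shifts to be representable on the trace grid. The exactness tests
therefore use dt = 0.05 s (TR = 1.05 s = 21 samples) and lags that are
multiples of the TR; with the default dt = 0.1 s, frame times fall
half-way between trace samples and nearest-neighbour rounding becomes
float-sensitive at the 1e-5 level. Sub-TR lags are recovered to one
interpolated grid step rather than exactly.

## ASL phantom and kinetic model

The perfusion-weighted difference signal follows the single-compartment
pCASL kinetic curve evaluated at the Look-Locker readout times
t = τ + PLD (τ = 1.65 s; PLDs 0.660/1.325/1.989/2.654 s):

    dM(t) = 0                                                      t < Δa
    dM(t) = K (1 − e^{−(t−Δa)/T1app})                   Δa ≤ t < Δa + τ
    dM(t) = K (1 − e^{−τ/T1app}) e^{−(t−Δa−τ)/T1app}        t ≥ Δa + τ
    K = 2 M0b (f/6000) α T1app e^{−Δa/T1b}

The repeated 25° readouts shorten the apparent relaxation:
1/T1app = 1/T1b − ln(cos θ)/ΔTI with ΔTI = 0.665 s (the printed PLD
spacing), T1b = 1.65 s, and labeling efficiency α = 0.85 × 0.95² ≈ 0.767
(two background-suppression pulses). Blood M0 is tissue M0 divided by the
partition coefficient λ = 0.9. Per-PLD M0 images follow saturation
recovery A(1 − e^{−t/T1*}) with per-tissue T1*; the equilibrium A
recovered by the surrogate-T1w fit is the M0 used in quantification, so
the noise-free phantom → reconstruction → inversion round trip is exact.

**Identifiability.** When the bolus has fully arrived before the first
readout (Δa < min(t) − τ ≈ 0.66 s for this protocol), every sample lies on
the decay plateau and (f, Δa) collapse onto the amplitude ridge
f·e^{Δa(1/T1app − 1/T1b)} = const: arrival time is then unidentifiable.
The generator draws arrival times above 0.7 s (physiologically sensible —
and the protocol's design implicitly assumes it), and the fitter flags
voxels with no signal as invalid rather than guessing.

**Inversion.** Flow enters the model linearly, so the fit uses variable
projection: for each candidate Δa the optimal f has a closed form
(clipped to f ∈ [0, 300] ml/100 ml/min), leaving a 1D residual in
Δa ∈ [0.1, 3.5] s that is minimized on a 0.05 s grid and polished by
vectorized golden-section search. This is deterministic, per-voxel
independent (no spatial prior), and is checked in the tests against an
exhaustive (f, Δa) lattice oracle. Pairwise outlier removal uses the
whole-volume mean difference per label/control pair: pairs deviating more
than 2.5 across-pair standard deviations are discarded — one concrete
reading of standard-deviation-based outlier rejection; tissue-variance
weighting is not implemented.

## BOLD conditioning

Fixed order: (1) temporal noise-to-signal (tNSR = sd/mean) masking —
voxels at or above the 98th linear-interpolation percentile of in-mask
tNSR are removed, so exactly 2% go when values are distinct and ties at
the threshold go too; constant voxels get tNSR = 0 and stay. (2) Bulk
alignment of the trace to the mean grey-matter series by maximizing
normalized cross-correlation over a ±max-shift window on the tr/4 grid
(integer multiples of the step, earliest on ties); a manual shift can be
supplied instead. (3) Nuisance GLM: intercept, linear drift, and any
motion trace with |Pearson r| > 0.3 against the GM mean — the absolute
value, since anticorrelated motion is equally nuisance; residuals keep
the intercept so baselines survive percent normalization. (4) Per-voxel
wavelet shrinkage: sym4 (near-symmetric, 8-tap), 4 levels, periodized,
soft universal threshold σ√(2 ln n) with σ from the finest-scale median
absolute deviation per voxel. (5) Anisotropic Gaussian smoothing with
FWHM 4×4×7 mm (matched to the effective ASL resolution), zero-padded and
renormalized inside the brain mask so edge voxels average brain signal
only. (6) Linear temporal interpolation ×4 (effective sampling 0.2625 s)
of both the series and the regressor, preserving original nodes exactly.

## CVR, lag, steal

CVR is the OLS slope of percent-normalized signal on the aligned PetCO2
regressor. Normalization default is the temporal mean; an optional
baseline-window mean (the pre-stimulus frames) is used by the pipeline
because the temporal mean includes the stimulus response and biases the
slope by a factor 1/(1 + cvr·ΔP̄/100) — a ~0.3% effect at typical values,
but enough to matter when checking exact recovery. Lag is the argmax of
|normalized correlation| against the regressor shifted over
[−5, +60] s by default (the studies here use [−5, +15] s on phantoms
whose true lags stay below 10 s) in steps of the interpolated dt, with
edge-hold padding, earliest lag on ties. The absolute value matters:
steal voxels respond with inverted sign, and a signed argmax would park
them at spurious shifts — the signed correlation at the chosen lag is
reported alongside. CVR is re-estimated with the optimally shifted
regressor and emitted for comparison, but steal segmentation and all
statistics use the bulk-aligned CVR, and steal is strictly cvr < 0
(exactly zero counts as non-steal).

## Statistics

CSF and treated (previously resected/irradiated) lesions are excluded
everywhere, together with tNSR-removed voxels. Tissue-ROI analysis:
per-subject mean/sd of each metric per tissue (GM, WM, edema, metastasis)
× steal status; Kruskal-Wallis H-tests on the per-subject means across
tissues (the design is paired between steal statuses, but the unpaired
test is kept deliberately — fidelity to the analysis being reproduced
over optimality), with Benjamini-Hochberg control at q = 0.05 over all
H-tests of one run, and Spearman correlations of per-subject means within
tissue. Binned analysis: in-mask AAT (or CBF) values are sorted and cut
into 20 bins of 5% each (sizes equal ±1; values tied across a boundary
fall to the lower bin; constant maps are rejected as degenerate); per-bin
means of all four maps feed the repeated-measures correlation, computed
by within-subject centering — r_rm = Σx̃ỹ/√(Σx̃²Σỹ²), slope Σx̃ỹ/Σx̃²,
df = N − k − 1, p from F(1, df) — equivalent to the two-model ANCOVA
sum-of-squares decomposition, against which it is tested to 1e-10 (and
cross-checked against an independent implementation). Voxelwise analysis:
per-subject Pearson r between map pairs within steal and non-steal masks
separately, with a group-level Wilcoxon signed-rank test against zero
(zero differences excluded, exact p for small n).

The per-patient cohort table bundled with the package reports means over
non-missing entries. One printed summary in the source material (mean
edema volume) is only reproduced by dividing the column sum by the full
cohort size despite missing entries; the package does not adopt that
convention and therefore reports 25.77 cc (n = 13), not 23.93.

## What the phantoms do and do not show

The generator reproduces the couplings the comparison is designed to
detect — spatial AAT gradients, CBF decreasing with AAT, lag increasing
with AAT, CVR increasing with CBF in non-steal tissue and decreasing with
CBF inside steal territory, with per-subject offsets that the
repeated-measures analysis absorbs. It does not emulate motion, EPI
distortion, bolus dispersion, macrovascular ASL signal, or realistic
spatial autocorrelation of noise. Passing the end-to-end tests therefore
shows that the pipeline's estimators recover the generated structure
through realistic noise levels (baseline/noise ≈ 50, i.e. block-response
SNR of order 1–2 per frame), not that the clinical acquisition chain is
free of those unmodeled effects. The steal-territory coupling is
deliberately weak (as it is in patients), and the cohort-level sign of
the steal CBF–CVR correlation is recovered in most but not every seeded
replicate — the acceptance suite requires ≥ 95% over 20 replicates, and
`scripts/acceptance.py` reports the observed rate for its own seed.

## Numerical details

* All randomness flows through `numpy.random.default_rng`/`SeedSequence`;
  identical seeds give bit-identical outputs, and pipeline reruns produce
  byte-identical tables.
* Correlation argmaxes break ties toward the earliest lag; bin boundaries
  break value ties toward the lower bin; a CVR of exactly zero is
  non-steal.
* Golden-section refinements run a fixed iteration count (typ. 40–45),
  narrowing the bracket below 1e-9 of its initial width — no
  tolerance-dependent early exit, for determinism.
* Degenerate inputs fail loudly: zero-variance regressors, flat GM
  series, empty masks, constant sorting maps, and invalid configurations
  raise typed errors; per-voxel degeneracies (no recovery contrast, zero
  difference signal) set validity flags instead.
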