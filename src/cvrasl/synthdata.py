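"""Synthetic breathing traces, BOLD/ASL phantoms and label maps.

Every downstream stage of the pipeline is exercised on phantoms generated
here with known ground truth: a hypercapnic block+ramp PetCO2 protocol, 4D
BOLD responses with prescribed per-voxel CVR amplitude (including negative
"vascular steal" values) and hemodynamic lag, and multi-PLD pCASL
label/control series generated from prescribed CBF/AAT maps through the
same kinetic forward model the quantification inverts.

The phantom forward model per brain voxel v at frame time t is

    S(v, t) = b(v) * [1 + cvr(v)/100 * (P(t - lag(v)) - P0)]
              + drift * t + noise

with P the PetCO2 trace (nearest-grid lookup), P0 the protocol baseline and
cvr in %BOLD/mmHg.  Lag acts as a pure temporal shift of the regressor;
dispersion is deliberately not modeled.  Large-vein voxels receive 10x the
noise standard deviation so that they exceed the temporal-noise cut used in
masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .asl_quant import kinetic_curve
from .core import AslAcquisitionParams, AslSeries, BoldSeries, BreathingTrace, LabelMap, Tissue

__all__ = [
    "BreathingProtocol",
    "GeometrySpec",
    "PhantomTruth",
    "generate_petco2_trace",
    "generate_label_map",
    "make_truth",
    "make_coupled_truth",
    "generate_bold_phantom",
    "generate_asl_phantom",
]

#: vein voxels get this multiple of the nominal noise level
VEIN_NOISE_FACTOR = 10.0


@dataclass
class BreathingProtocol:
    """Block + ramp hypercapnic protocol (durations s, amplitudes mmHg).

    Defaults follow the clinical protocol: 5-minute baseline, +10 mmHg
    block for 90 s, 120 s recovery, linear ramp to +12 mmHg over 180 s,
    90 s tail at baseline.
    """

    baseline_duration: float = 300.0
    block_amplitude: float = 10.0
    block_duration: float = 90.0
    inter_duration: float = 120.0
    ramp_amplitude: float = 12.0
    ramp_duration: float = 180.0
    tail_duration: float = 90.0
    baseline_petco2: float = 40.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "block_duration", "inter_duration",
                     "ramp_duration", "tail_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.block_amplitude < 0 or self.ramp_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def total_duration(self) -> float:
        return (self.baseline_duration + self.block_duration + self.inter_duration
                + self.ramp_duration + self.tail_duration)


def generate_petco2_trace(protocol: BreathingProtocol,
                          dt: float = 0.1,
                          noise_sd: float = 0.0,
                          seed: int | None = None) -> BreathingTrace:
    """Sample the protocol's piecewise PetCO2 target on a uniform grid.

    The ramp rises linearly and reaches exactly baseline + ramp_amplitude at
    its final sample; additive white noise with standard deviation
    ``noise_sd`` emulates breath-to-breath variability.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(protocol.total_duration / dt))
    t = np.arange(n) * dt
    p = np.full(n, protocol.baseline_petco2)

    b0 = protocol.baseline_duration
    b1 = b0 + protocol.block_duration
    r0 = b1 + protocol.inter_duration
    r1 = r0 + protocol.ramp_duration

    block = (t >= b0) & (t < b1)
    p[block] = protocol.baseline_petco2 + protocol.block_amplitude
    ramp = (t >= r0) & (t < r1)
    frac = (t[ramp] - r0 + dt) / protocol.ramp_duration
    p[ramp] = protocol.baseline_petco2 + protocol.ramp_amplitude * frac

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sd, size=n)
    return BreathingTrace(time=t, petco2=p)


@dataclass
class GeometrySpec:
    """Geometry of the digital head phantom (all sizes in voxels/fractions).

    The brain is an inscribed ellipsoid; a central ellipsoid is CSF
    (ventricles), the deep remainder WM, the outer shell GM.  A metastasis
    sphere with a surrounding edema shell, a treated-lesion sphere, randomly
    scattered vein voxels, and a spherical steal territory (fraction of the
    brain volume) complete the picture.
    """

    csf_fraction: float = 0.15       # of brain radius
    gm_shell: float = 0.62           # normalized radius where GM starts
    metastasis_radius: float = 1.6   # voxels
    edema_radius: float = 3.0        # voxels (shell around metastasis)
    treated_radius: float = 1.4      # voxels; 0 disables
    n_vein_voxels: int = 8
    steal_fraction: float = 0.12     # of brain volume; 0 disables


def _sphere(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def generate_label_map(shape: tuple[int, int, int],
                       geometry: GeometrySpec | None = None,
                       seed: int = 0) -> LabelMap:
    """Build a deterministic tissue/lesion label map with a steal flag.

    Labels partition the grid (every voxel carries exactly one tissue
    integer); the steal territory is a separate boolean flag restricted to
    analyzable brain tissue.
    """
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    geo = geometry or GeometrySpec()
    rng = np.random.default_rng(seed)

    half = np.array([(s - 1) / 2.0 for s in shape])
    radii = np.maximum(half * 0.95, 0.5)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, half, radii))
    brain = r2 <= 1.0
    if not brain.any():
        raise ValueError("grid too small to contain a brain ellipsoid")

    labels = np.zeros(shape, dtype=np.int16)
    rnorm = np.sqrt(r2)
    labels[brain & (rnorm <= geo.csf_fraction)] = Tissue.CSF
    labels[brain & (rnorm > geo.csf_fraction) & (rnorm <= geo.gm_shell)] = Tissue.WM
    labels[brain & (rnorm > geo.gm_shell)] = Tissue.GM

    def random_brain_center():
        idx = np.argwhere(brain & (rnorm > geo.csf_fraction) & (rnorm < 0.85))
        return idx[rng.integers(len(idx))]

    if geo.metastasis_radius > 0:
        c = random_brain_center()
        edema = _sphere(shape, c, geo.edema_radius) & brain
        if not edema.any():
            raise ValueError("edema region does not fit the grid")
        met = _sphere(shape, c, geo.metastasis_radius) & brain
        labels[edema & (labels != Tissue.CSF)] = Tissue.EDEMA
        labels[met & (labels != Tissue.CSF)] = Tissue.METASTASIS

    if geo.treated_radius > 0:
        c = random_brain_center()
        treated = _sphere(shape, c, geo.treated_radius) & brain
        labels[treated & ~np.isin(labels, [Tissue.CSF, Tissue.METASTASIS])] = \
            Tissue.TREATED_LESION

    if geo.n_vein_voxels > 0:
        candidates = np.argwhere(np.isin(labels, [Tissue.GM, Tissue.WM]))
        if geo.n_vein_voxels > len(candidates):
            raise ValueError("more vein voxels requested than available tissue")
        pick = candidates[rng.choice(len(candidates), geo.n_vein_voxels,
                                     replace=False)]
        labels[tuple(pick.T)] = Tissue.VEIN

    steal = np.zeros(shape, dtype=bool)
    if geo.steal_fraction > 0:
        target = geo.steal_fraction * brain.sum()
        if target < 1:
            raise ValueError("steal fraction too small for this grid")
        radius = (3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0)
        c = random_brain_center()
        region = _sphere(shape, c, radius)
        steal = region & np.isin(labels, [int(t) for t in
                                          (Tissue.GM, Tissue.WM, Tissue.EDEMA,
                                           Tissue.METASTASIS)])
        if not steal.any():
            raise ValueError("steal region does not overlap analyzable tissue")
    return LabelMap(data=labels, steal=steal)


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps the phantoms are generated from.

    cvr_true in %BOLD/mmHg (negative inside steal territory), lag_true in s,
    cbf_true in ml/100 ml/min, aat_true in s, t1_true the tissue T1* (s)
    driving the M0 saturation recovery, baseline_signal the BOLD baseline
    per voxel (a.u.).
    """

    cvr_true: np.ndarray
    lag_true: np.ndarray
    cbf_true: np.ndarray
    aat_true: np.ndarray
    t1_true: np.ndarray
    labels: LabelMap
    baseline_signal: np.ndarray
    noise_sd: float = 0.0
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = self.labels.data.shape
        for name in ("cvr_true", "lag_true", "cbf_true", "aat_true",
                     "t1_true", "baseline_signal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape must match label map")
            setattr(self, name, arr)
        brain = self.labels.brain_mask
        if np.any(self.lag_true[brain] < 0):
            raise ValueError("lag_true must be non-negative")
        if np.any(self.cbf_true[brain] < 0):
            raise ValueError("cbf_true must be non-negative")
        if np.any(self.aat_true[brain] <= 0):
            raise ValueError("aat_true must be positive")
        if np.any(self.cvr_true[self.labels.steal] >= 0):
            raise ValueError("steal-labeled voxels must have cvr_true < 0")


#: per-tissue generative defaults: (cbf ml/100ml/min, aat s, cvr %/mmHg,
#: lag s, T1* s).  GM CBF is drawn inside the 30-50 range typical of PET
#: and multi-delay ASL grey matter; WM/edema values follow the qualitative
#: ordering reported for brain-metastases cohorts (edema: low flow, long
#: arrival, sluggish reactivity).
TISSUE_DEFAULTS = {
    Tissue.GM: (45.0, 0.9, 0.20, 2.0, 1.30),
    Tissue.WM: (22.0, 1.4, 0.10, 4.0, 0.85),
    Tissue.EDEMA: (14.0, 1.7, 0.05, 6.0, 1.50),
    Tissue.METASTASIS: (50.0, 1.1, 0.12, 3.0, 1.20),
    Tissue.CSF: (5.0, 2.0, 0.02, 1.0, 3.50),
    Tissue.TREATED_LESION: (12.0, 1.8, 0.04, 5.0, 1.10),
    Tissue.VEIN: (45.0, 0.9, 0.30, 8.0, 1.60),
}


def make_truth(labels: LabelMap,
               seed: int = 0,
               noise_sd: float = 0.0,
               drift_slope: float = 0.0,
               baseline_signal: float = 1000.0,
               jitter: float = 0.10,
               steal_cvr: float = -0.08,
               lag_on_tr_grid: float | None = None) -> PhantomTruth:
    """Fill per-tissue ground truth with multiplicative spatial jitter.

    Steal-flagged voxels get cvr_true around ``steal_cvr`` (always < 0).
    If ``lag_on_tr_grid`` is given, lags are snapped to multiples of that
    spacing (useful for exact recovery checks on the sampling grid).
    """
    rng = np.random.default_rng(seed)
    shape = labels.data.shape
    cvr = np.zeros(shape)
    lag = np.zeros(shape)
    cbf = np.zeros(shape)
    aat = np.full(shape, 1.0)
    t1 = np.full(shape, 1.0)
    base = np.zeros(shape)

    for tissue, (f0, a0, c0, l0, t10) in TISSUE_DEFAULTS.items():
        m = labels.data == int(tissue)
        if not m.any():
            continue
        n = int(m.sum())
        jit = lambda v, lo=None: np.clip(
            v * (1.0 + jitter * rng.standard_normal(n)),
            lo if lo is not None else v * 0.3, None)
        cbf[m] = jit(f0, lo=0.0)
        # arrival times below min(readout) - tau (~0.66 s for this protocol)
        # are pure amplitude ridges in the kinetic model; stay above them
        aat[m] = jit(a0, lo=0.7)
        cvr[m] = c0 * (1.0 + jitter * rng.standard_normal(n))
        lag[m] = np.clip(l0 * (1.0 + jitter * rng.standard_normal(n)), 0.0, None)
        t1[m] = jit(t10, lo=0.2)
        base[m] = baseline_signal * (1.0 + 0.05 * rng.standard_normal(n))

    st = labels.steal
    if st.any():
        cvr[st] = -np.abs(steal_cvr * (1.0 + jitter * rng.standard_normal(int(st.sum()))))
    # keep non-steal analyzable tissue non-negative so steal <-> cvr<0 exactly
    analyzable = labels.mask(Tissue.GM, Tissue.WM, Tissue.EDEMA, Tissue.METASTASIS)
    nonsteal = analyzable & ~st
    cvr[nonsteal] = np.abs(cvr[nonsteal])

    if lag_on_tr_grid is not None:
        lag = np.round(lag / lag_on_tr_grid) * lag_on_tr_grid
    return PhantomTruth(cvr_true=cvr, lag_true=lag, cbf_true=cbf, aat_true=aat,
                        t1_true=t1, labels=labels, baseline_signal=base,
                        noise_sd=noise_sd, drift_slope=drift_slope, seed=seed)


def make_coupled_truth(labels: LabelMap,
                       seed: int = 0,
                       noise_sd: float = 20.0,
                       drift_slope: float = 0.05,
                       baseline_signal: float = 1000.0) -> PhantomTruth:
    """Ground truth with the physiological couplings seen in patients.

    Within each subject's analyzable tissue:

    * AAT varies spatially (short in GM, long in WM/edema);
    * CBF decreases with AAT (well-perfused tissue has early arrival);
    * hemodynamic lag increases with AAT, hence decreases with CBF;
    * non-steal voxels: CVR increases with CBF (intact autoregulation);
    * steal voxels: CVR is negative and grows *more* negative with CBF —
      the inverted coupling of exhausted-reserve territory.

    Per-subject random offsets (arrival time, flow level, reactivity gain,
    lag intercept) create the between-subject variance that the
    repeated-measures correlation is designed to absorb.
    """
    rng = np.random.default_rng(seed)
    shape = labels.data.shape
    truth = make_truth(labels, seed=seed, noise_sd=noise_sd,
                       drift_slope=drift_slope,
                       baseline_signal=baseline_signal)

    # subject-level offsets
    aat_off = rng.normal(0.0, 0.12)
    cbf_off = rng.normal(0.0, 4.0)
    cvr_gain = 1.0 + rng.normal(0.0, 0.15)
    lag_off = rng.normal(0.0, 0.5)

    analyz = labels.mask(Tissue.GM, Tissue.WM, Tissue.EDEMA, Tissue.METASTASIS)
    n = int(analyz.sum())
    aat = truth.aat_true.copy()
    aat[analyz] = np.clip(aat[analyz] + aat_off + rng.normal(0, 0.05, n),
                          0.7, 3.2)
    cbf = np.zeros(shape)
    cbf[analyz] = np.clip(55.0 + cbf_off - 22.0 * (aat[analyz] - 1.0)
                          + rng.normal(0, 2.5, n), 3.0, None)
    lag = np.zeros(shape)
    lag[analyz] = np.clip(1.0 + lag_off + 3.0 * (aat[analyz] - 0.5)
                          + rng.normal(0, 0.3, n), 0.0, 14.0)
    cvr = np.zeros(shape)
    nonsteal = analyz & ~labels.steal
    cvr[nonsteal] = np.clip(
        cvr_gain * 0.004 * cbf[nonsteal]
        + rng.normal(0, 0.008, int(nonsteal.sum())), 1e-4, None)
    st = labels.steal
    if st.any():
        cvr[st] = -np.clip(
            cvr_gain * 0.0025 * cbf[st]
            + rng.normal(0, 0.006, int(st.sum())), 1e-4, None)

    return PhantomTruth(cvr_true=cvr, lag_true=lag, cbf_true=cbf,
                        aat_true=aat, t1_true=truth.t1_true, labels=labels,
                        baseline_signal=truth.baseline_signal,
                        noise_sd=noise_sd, drift_slope=drift_slope, seed=seed)


def generate_bold_phantom(truth: PhantomTruth,
                          trace: BreathingTrace,
                          tr: float = 1.05,
                          n_volumes: int | None = None,
                          baseline_petco2: float | None = None,
                          voxel_size: tuple[float, float, float] = (2.292, 2.292, 2.5),
                          ) -> BoldSeries:
    """Forward-model a 4D BOLD series from ground truth and a PetCO2 trace.

    ``baseline_petco2`` defaults to the first trace sample (the protocol
    baseline).  The trace must cover the sampled window; lagged lookups
    before the trace start clamp to the baseline value.
    """
    if n_volumes is None:
        n_volumes = int(np.floor(trace.duration / tr))
    if n_volumes < 2:
        raise ValueError("need at least two volumes")
    t_last = (n_volumes - 1) * tr
    if t_last > trace.time[-1] + 1e-9:
        raise ValueError("trace too short for the requested BOLD window")
    p0 = trace.petco2[0] if baseline_petco2 is None else baseline_petco2

    shape = truth.labels.data.shape
    brain = truth.labels.brain_mask
    frame_t = np.arange(n_volumes) * tr

    rng = np.random.default_rng(truth.seed)
    data = np.zeros(shape + (n_volumes,))

    vox = np.argwhere(brain)
    lags = truth.lag_true[brain]
    # stimulus excess per voxel/frame, via the shared nearest-grid lookup
    shifted = frame_t[None, :] - lags[:, None]
    pvals = trace.sample(shifted) - p0  # (n_brain, n_t)
    sig = truth.baseline_signal[brain][:, None] * (
        1.0 + truth.cvr_true[brain][:, None] / 100.0 * pvals)
    if truth.drift_slope != 0.0:
        sig = sig + truth.drift_slope * frame_t[None, :]
    if truth.noise_sd > 0:
        sd = np.full(len(vox), truth.noise_sd)
        sd[truth.labels.data[brain] == int(Tissue.VEIN)] *= VEIN_NOISE_FACTOR
        sig = sig + rng.normal(0.0, 1.0, sig.shape) * sd[:, None]
    data[brain] = sig
    return BoldSeries(data=data, tr=tr, voxel_size=voxel_size, brain_mask=brain)


def generate_asl_phantom(truth: PhantomTruth,
                         params: AslAcquisitionParams | None = None,
                         m0_value: float = 1000.0,
                         noise_sd: float = 0.0,
                         n_pairs: int = 23,
                         seed: int | None = None) -> AslSeries:
    """Forward-model a multi-PLD label/control series from CBF/AAT truth.

    Per-PLD M0 images follow saturation recovery M0(t) = A (1 - e^(-t/T1*))
    with the per-voxel T1* of the truth; the noise-free control - label
    difference at each PLD equals the kinetic curve evaluated at
    (cbf_true, aat_true) with blood M0 = A / lambda.
    """
    params = params or AslAcquisitionParams()
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    shape = truth.labels.data.shape
    brain = truth.labels.brain_mask
    n_plds = len(params.plds)
    plds = np.asarray(params.plds)

    a_map = np.where(brain, m0_value, 0.0)
    t1 = np.where(brain, truth.t1_true, 1.0)
    m0 = a_map[None] * (1.0 - np.exp(-plds[:, None, None, None] / t1[None]))

    t = params.readout_times
    dm = np.zeros((n_plds,) + shape)
    dm[:, brain] = kinetic_curve(
        t[:, None], truth.cbf_true[brain][None, :],
        truth.aat_true[brain][None, :], params,
        a_map[brain][None, :] / params.lambda_blood)

    control = np.broadcast_to(m0, (n_pairs,) + m0.shape).copy()
    label = control - dm[None]
    if noise_sd > 0:
        control = control + rng.normal(0.0, noise_sd, control.shape)
        label = label + rng.normal(0.0, noise_sd, label.shape)
    return AslSeries(label=label, control=control, m0=m0, params=params)
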