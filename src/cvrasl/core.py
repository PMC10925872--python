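"""Shared data containers for the BOLD-CVR / multi-delay ASL comparison pipeline.

Everything downstream operates on a handful of small dataclasses wrapping
numpy arrays: a 4D BOLD series, a multi-PLD ASL series, 3D parameter maps
(CVR, hemodynamic lag, CBF, AAT), integer tissue label maps, and the
end-tidal CO2 stimulus trace.  Volumes are voxel-indexed; geometry is
carried only as the voxel size (the pipeline assumes co-registered inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Tissue",
    "BreathingTrace",
    "BoldSeries",
    "AslAcquisitionParams",
    "AslSeries",
    "ParameterMap",
    "LabelMap",
]


class Tissue(IntEnum):
    """Integer labels used in tissue/lesion label maps."""

    BACKGROUND = 0
    GM = 1
    WM = 2
    EDEMA = 3
    METASTASIS = 4
    CSF = 5
    TREATED_LESION = 6
    VEIN = 7


#: tissues that enter the comparative analyses (brain matter, edema,
#: untreated metastases); CSF and treated lesions are always excluded.
ANALYZED_TISSUES = (Tissue.GM, Tissue.WM, Tissue.EDEMA, Tissue.METASTASIS)


@dataclass
class BreathingTrace:
    """End-tidal CO2 trace sampled on a uniform time grid.

    Attributes
    ----------
    time : (n,) array, seconds, strictly increasing and uniform.
    petco2 : (n,) array, mmHg.
    """

    time: np.ndarray
    petco2: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.petco2 = np.asarray(self.petco2, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.petco2.shape:
            raise ValueError("time and petco2 must be 1D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("trace time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace time grid must be uniform")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.petco2))):
            raise ValueError("trace contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Total covered duration (n samples x dt)."""
        return self.time.size * self.dt

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Nearest-grid-point lookup of the trace at arbitrary times.

        Times outside the covered interval clamp to the first/last sample;
        this is the single sampling rule shared by the phantom generator and
        the regressor-resampling steps, so noise-free round trips are exact.
        """
        idx = np.rint((np.asarray(times, dtype=float) - self.time[0]) / self.dt)
        idx = np.clip(idx.astype(np.int64), 0, self.time.size - 1)
        return self.petco2[idx]

    def shifted(self, shift_s: float) -> "BreathingTrace":
        """Trace translated forward in time by ``shift_s`` seconds."""
        return BreathingTrace(self.time + shift_s, self.petco2.copy())


@dataclass
class BoldSeries:
    """4D BOLD signal with acquisition metadata.

    data has shape (x, y, z, t); tr in seconds; voxel_size in mm;
    brain_mask is a boolean 3D array matching the spatial shape.
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive numbers (mm)")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape must match spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def with_data(self, data: np.ndarray, tr: float | None = None) -> "BoldSeries":
        return BoldSeries(data, self.tr if tr is None else tr,
                          self.voxel_size, self.brain_mask)


@dataclass
class AslAcquisitionParams:
    """Multi-PLD pCASL Look-Locker acquisition parameters.

    plds : post-labeling delays in seconds, ascending.
    tau : labeling train duration, s.
    flip_deg : Look-Locker readout flip angle, degrees.
    alpha : labeling efficiency (including background-suppression losses).
    t1b : longitudinal relaxation time of arterial blood, s.
    dti : Look-Locker readout spacing, s.
    lambda_blood : blood-brain partition coefficient (ml/ml) used to scale
        tissue M0 to blood M0.
    """

    plds: tuple[float, ...] = (0.660, 1.325, 1.989, 2.654)
    tau: float = 1.650
    flip_deg: float = 25.0
    alpha: float = 0.85 * 0.95 ** 2
    t1b: float = 1.65
    dti: float = 0.665
    lambda_blood: float = 0.9

    def __post_init__(self) -> None:
        self.plds = tuple(float(p) for p in self.plds)
        if len(self.plds) == 0:
            raise ValueError("PLD list must not be empty")
        if any(b <= a for a, b in zip(self.plds, self.plds[1:])):
            raise ValueError("PLDs must be strictly ascending")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("labeling efficiency must lie in (0, 1]")
        if not (0.0 < self.flip_deg < 90.0):
            raise ValueError("flip angle must lie in (0, 90) degrees")
        if self.tau <= 0 or self.t1b <= 0 or self.dti <= 0:
            raise ValueError("tau, t1b and dti must be positive")

    @property
    def t1_app(self) -> float:
        """Apparent T1 under the Look-Locker readout.

        Repeated small-flip excitations accelerate the effective decay:
        1/T1app = 1/T1b - ln(cos theta)/dTI.
        """
        return 1.0 / (1.0 / self.t1b
                      - math.log(math.cos(math.radians(self.flip_deg))) / self.dti)

    @property
    def readout_times(self) -> np.ndarray:
        """Times of the readouts measured from the start of labeling (tau + PLD)."""
        return self.tau + np.asarray(self.plds)


@dataclass
class AslSeries:
    """Label/control pairs per PLD plus per-PLD M0 images.

    label, control : arrays of shape (n_pairs, n_plds, x, y, z).
    m0 : array of shape (n_plds, x, y, z) — the pair acquired with labeling
        and background suppression off.
    """

    label: np.ndarray
    control: np.ndarray
    m0: np.ndarray
    params: AslAcquisitionParams

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.label.shape != self.control.shape:
            raise ValueError("label and control shapes must match")
        if self.label.ndim != 5:
            raise ValueError("label/control must have shape (pairs, plds, x, y, z)")
        if self.label.shape[0] < 1:
            raise ValueError("need at least one label/control pair")
        if self.m0.shape != self.label.shape[1:]:
            raise ValueError("m0 must have shape (plds, x, y, z)")
        if self.label.shape[1] != len(self.params.plds):
            raise ValueError("PLD axis must match params.plds")

    @property
    def n_pairs(self) -> int:
        return self.label.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.label.shape[2:]


@dataclass
class ParameterMap:
    """3D map of one hemodynamic quantity with units."""

    data: np.ndarray
    name: str
    units: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("parameter map must be 3D")


@dataclass
class LabelMap:
    """Integer tissue/lesion labels, with an optional steal sub-region flag.

    The steal flag is cross-cutting (a GM voxel may or may not sit in a
    steal territory), so it is carried as a separate boolean volume rather
    than extra label integers.
    """

    data: np.ndarray
    steal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must hold integers")
        if self.data.ndim != 3:
            raise ValueError("label map must be 3D")
        if self.steal is None:
            self.steal = np.zeros(self.data.shape, dtype=bool)
        self.steal = np.asarray(self.steal, dtype=bool)
        if self.steal.shape != self.data.shape:
            raise ValueError("steal flag shape must match label shape")

    def mask(self, *tissues: Tissue) -> np.ndarray:
        return np.isin(self.data, [int(t) for t in tissues])

    @property
    def brain_mask(self) -> np.ndarray:
        return self.data != int(Tissue.BACKGROUND)
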