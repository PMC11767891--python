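"""Core domain types shared across the package.

The time-domain record (:class:`Fid`) and the frequency-domain record
(:class:`Spectrum1D`) are thin dataclasses around numpy arrays; all
processing operations live in :mod:`nmlab.spec1d` and return new objects
rather than mutating in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

__all__ = ["AcqPars", "ProcPars", "Fid", "Spectrum1D"]


@dataclass
class AcqPars:
    """Acquisition parameters of a 1D experiment.

    Parameters
    ----------
    spectral_width_hz : float
        Full sweep width in Hz (> 0).
    spectrometer_freq_mhz : float
        Observe frequency in MHz (> 0).
    n_points_td : int
        Number of acquired *complex* time-domain points (>= 2).
    carrier_offset_hz : float
        Transmitter offset from 0 ppm, in Hz.
    group_delay : float
        Digital-filter group delay in points; may be fractional.
    pulse_program : str
        Pulse program name as recorded by the spectrometer.
    byte_order : str
        ``"little"`` or ``"big"`` -- binary dialect of the raw data file.
    int_size : int
        Integer width in bytes for integer-encoded raw data.
    data_type : str
        ``"int32"`` or ``"float64"`` raw data encoding.
    title : str
        Free-text experiment title (may be empty).
    """

    spectral_width_hz: float
    spectrometer_freq_mhz: float
    n_points_td: int
    carrier_offset_hz: float = 0.0
    group_delay: float = 0.0
    pulse_program: str = ""
    byte_order: str = "little"
    int_size: int = 4
    data_type: str = "int32"
    title: str = ""

    def __post_init__(self) -> None:
        if not self.spectral_width_hz > 0:
            raise InputError(f"spectral_width_hz must be > 0, got {self.spectral_width_hz}")
        if not self.spectrometer_freq_mhz > 0:
            raise InputError(f"spectrometer_freq_mhz must be > 0, got {self.spectrometer_freq_mhz}")
        if self.n_points_td < 2:
            raise InputError(f"n_points_td must be >= 2, got {self.n_points_td}")
        if self.group_delay < 0:
            raise InputError(f"group_delay must be >= 0, got {self.group_delay}")
        if self.byte_order not in ("little", "big"):
            raise InputError(f"byte_order must be 'little' or 'big', got {self.byte_order!r}")
        if self.data_type not in ("int32", "float64"):
            raise InputError(f"data_type must be 'int32' or 'float64', got {self.data_type!r}")

    @property
    def dwell_s(self) -> float:
        """Sampling interval in seconds (1 / spectral width)."""
        return 1.0 / self.spectral_width_hz

    @property
    def sweep_ppm(self) -> float:
        return self.spectral_width_hz / self.spectrometer_freq_mhz

    @property
    def carrier_ppm(self) -> float:
        return self.carrier_offset_hz / self.spectrometer_freq_mhz

    def to_dict(self) -> dict:
        return {
            "spectral_width_hz": self.spectral_width_hz,
            "spectrometer_freq_mhz": self.spectrometer_freq_mhz,
            "n_points_td": self.n_points_td,
            "carrier_offset_hz": self.carrier_offset_hz,
            "group_delay": self.group_delay,
            "pulse_program": self.pulse_program,
            "byte_order": self.byte_order,
            "int_size": self.int_size,
            "data_type": self.data_type,
            "title": self.title,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcqPars":
        return cls(**d)


#: water-suppression modes accepted by :class:`ProcPars`
WATER_MODES = ("none", "poly", "conv_gauss", "conv_sine", "wavelet")
REFERENCE_MODES = ("tmsp", "water", "manual")


@dataclass
class ProcPars:
    """Processing options attached to a spectrum."""

    zero_fill_size: int = 0
    line_broadening_hz: float = 0.0
    phi0_deg: float = 0.0
    phi1_deg: float = 0.0
    water_suppression_mode: str = "none"
    reference_mode: str = "manual"
    reference_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.line_broadening_hz < 0:
            raise InputError(f"line_broadening_hz must be >= 0, got {self.line_broadening_hz}")
        if self.water_suppression_mode not in WATER_MODES:
            raise InputError(
                f"water_suppression_mode must be one of {WATER_MODES}, got {self.water_suppression_mode!r}"
            )
        if self.reference_mode not in REFERENCE_MODES:
            raise InputError(
                f"reference_mode must be one of {REFERENCE_MODES}, got {self.reference_mode!r}"
            )

    def to_dict(self) -> dict:
        return {
            "zero_fill_size": self.zero_fill_size,
            "line_broadening_hz": self.line_broadening_hz,
            "phi0_deg": self.phi0_deg,
            "phi1_deg": self.phi1_deg,
            "water_suppression_mode": self.water_suppression_mode,
            "reference_mode": self.reference_mode,
            "reference_ppm": self.reference_ppm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProcPars":
        return cls(**d)


@dataclass
class Fid:
    """Complex time-domain record plus its acquisition parameters."""

    points: np.ndarray
    acq: AcqPars

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.complex128)
        if self.points.ndim != 1 or self.points.size < 2:
            raise InputError("fid must hold at least 2 complex points")

    @property
    def dwell_s(self) -> float:
        return self.acq.dwell_s

    def copy_with(self, points: np.ndarray) -> "Fid":
        return Fid(points=np.asarray(points, dtype=np.complex128), acq=self.acq)

    def __len__(self) -> int:
        return self.points.size


@dataclass
class Spectrum1D:
    """Complex frequency-domain record with a descending ppm axis.

    ``phi0_deg`` / ``phi1_deg`` accumulate the phase corrections applied so
    far; ``log`` records every processing step in order.
    """

    points: np.ndarray
    ppm_axis: np.ndarray
    phi0_deg: float = 0.0
    phi1_deg: float = 0.0
    proc: ProcPars = field(default_factory=ProcPars)
    acq: AcqPars | None = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.complex128)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=np.float64)
        if self.ppm_axis.shape != self.points.shape:
            raise InputError("ppm_axis and points must have identical length")
        if self.ppm_axis.size >= 2 and not np.all(np.diff(self.ppm_axis) < 0):
            raise InputError("ppm_axis must be strictly decreasing")
        if not (math.isfinite(self.phi0_deg) and math.isfinite(self.phi1_deg)):
            raise InputError("phase values must be finite")

    @property
    def real(self) -> np.ndarray:
        return self.points.real

    @property
    def n_points(self) -> int:
        return self.points.size

    @property
    def ppm_spacing(self) -> float:
        """Absolute ppm distance between adjacent points."""
        return float(abs(self.ppm_axis[0] - self.ppm_axis[-1]) / (self.ppm_axis.size - 1))

    def copy(self, **changes) -> "Spectrum1D":
        base = dict(
            points=self.points.copy(),
            ppm_axis=self.ppm_axis.copy(),
            phi0_deg=self.phi0_deg,
            phi1_deg=self.phi1_deg,
            proc=replace(self.proc),
            acq=self.acq,
            log=list(self.log),
        )
        base.update(changes)
        return Spectrum1D(**base)

    def index_of_ppm(self, ppm: float) -> int:
        """Index of the axis point closest to ``ppm``."""
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))

    def window_indices(self, low_ppm: float, high_ppm: float) -> np.ndarray:
        """Indices with ppm in the half-open interval [low_ppm, high_ppm)."""
        if high_ppm < low_ppm:
            high_ppm, low_ppm = low_ppm, high_ppm
        mask = (self.ppm_axis >= low_ppm) & (self.ppm_axis < high_ppm)
        return np.nonzero(mask)[0]
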