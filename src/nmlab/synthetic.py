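"""Deterministic, seeded generation of every test input.

All generators are pure functions of their spec and seed: re-running with
the same arguments reproduces outputs bit-identically. Ground-truth
quantities (phase distortions, segment shifts, dilution factors) are
returned alongside the data so recovery tests never re-derive them.

The default acquisition emulates a 600 MHz instrument with a ~12 ppm sweep
centered at 4.7 ppm; this puts usable signal-free baseline regions beyond
10 ppm and below -0.5 ppm on the axis, as the autophase module expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AcqPars, Fid
from .errors import InputError
from .hsqc import MetaboliteEntry, build_multiplet_model, _lorentzian
from .isotopomer import IsotopomerDistribution, forward_multiplet
from .preprocess import SpectraSet
from .spec1d import apodize_exponential, fourier_transform, zero_fill

__all__ = [
    "PeakSpec",
    "SeriesSpec",
    "default_acq",
    "metabolite_mix_peaks",
    "gen_fid",
    "gen_series",
    "gen_multiplet_trace",
    "gen_bruker_fixture",
]


def default_acq(n_points: int = 32768, group_delay: float = 0.0,
                title: str = "") -> AcqPars:
    """600 MHz-style acquisition: 7211.54 Hz sweep, carrier at 4.7 ppm."""
    return AcqPars(
        spectral_width_hz=7211.54,
        spectrometer_freq_mhz=600.13,
        n_points_td=n_points,
        carrier_offset_hz=4.7 * 600.13,
        group_delay=group_delay,
        pulse_program="noesygppr1d",
        title=title,
    )


@dataclass
class PeakSpec:
    """One Lorentzian resonance (optionally a stick multiplet)."""

    ppm: float
    amplitude: float = 1.0
    linewidth_hz: float = 1.2
    sticks: list | None = None  # (hz_offset, weight) pairs

    def __post_init__(self) -> None:
        if self.linewidth_hz <= 0:
            raise InputError("linewidth must be > 0")
        if self.amplitude < 0:
            raise InputError("amplitude must be >= 0")


def metabolite_mix_peaks() -> list:
    """A small urea/creatinine/alanine/isoleucine/TMSP-like peak set."""
    return [
        PeakSpec(ppm=0.00, amplitude=0.5, linewidth_hz=1.0),  # reference singlet
        PeakSpec(ppm=0.94, amplitude=0.25, linewidth_hz=1.3,
                 sticks=[(-3.7, 0.5), (3.7, 0.5)]),
        PeakSpec(ppm=1.48, amplitude=0.7, linewidth_hz=1.2,
                 sticks=[(-3.6, 0.5), (3.6, 0.5)]),
        PeakSpec(ppm=3.05, amplitude=0.8, linewidth_hz=1.2),
        PeakSpec(ppm=4.06, amplitude=0.6, linewidth_hz=1.2),
        PeakSpec(ppm=5.80, amplitude=1.0, linewidth_hz=1.6),
    ]


def gen_fid(peaks: list, acq: AcqPars | None = None, noise_sd: float = 0.0,
            seed: int = 0) -> Fid:
    """Sum of exponentially decaying complex sinusoids plus circular noise.

    Frequencies follow from each peak's ppm position relative to the
    carrier; decay rates from the Lorentzian linewidth. Deterministic for a
    given seed.
    """
    acq = acq or default_acq()
    lo = acq.carrier_ppm - acq.sweep_ppm / 2
    hi = acq.carrier_ppm + acq.sweep_ppm / 2
    t = np.arange(acq.n_points_td) * acq.dwell_s
    fid = np.zeros(acq.n_points_td, dtype=np.complex128)
    for pk in peaks:
        if not (lo < pk.ppm < hi):
            raise InputError(f"peak at {pk.ppm} ppm outside window ({lo:.2f}, {hi:.2f})")
        sticks = pk.sticks or [(0.0, 1.0)]
        base_hz = pk.ppm * acq.spectrometer_freq_mhz - acq.carrier_offset_hz
        decay = np.exp(-np.pi * pk.linewidth_hz * t)
        for off_hz, weight in sticks:
            fid += pk.amplitude * weight * decay * np.exp(2j * np.pi * (base_hz + off_hz) * t)
    # half-weight the t=0 sample so the discrete spectrum has a flat zero
    # baseline (the usual first-point convention, applied at generation)
    fid[0] *= 0.5
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + noise_sd * (rng.standard_normal(t.size) + 1j * rng.standard_normal(t.size))
    return Fid(points=fid, acq=acq)


@dataclass
class SeriesSpec:
    """Recipe for a series of sibling spectra with known distortions."""

    n_spectra: int
    peaks: list = field(default_factory=metabolite_mix_peaks)
    phase_errors: list | None = None  # (phi0, phi1) per spectrum
    segment_shifts: list | None = None  # ppm displacement per spectrum
    shifted_peaks: list = field(default_factory=list)  # indices into peaks
    dilution_factors: list | None = None
    baseline_polys: list | None = None  # polynomial coefficients per spectrum
    noise_sd: float = 0.0
    seed: int = 0
    acq: AcqPars | None = None
    lb_hz: float = 0.0
    zero_fill_to: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        for name in ("phase_errors", "segment_shifts", "dilution_factors", "baseline_polys"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_spectra:
                raise InputError(f"{name} must have one entry per spectrum")


def gen_series(spec: SeriesSpec):
    """Generate a :class:`SpectraSet` plus the ground truth used to build it.

    Per-spectrum phase errors are applied in the frequency domain without
    being recorded in the phase state (they model unknown instrument
    distortions); segment shifts displace only the designated peaks;
    dilution factors scale all intensities.
    """
    acq = spec.acq or default_acq()
    spectra = []
    for j in range(spec.n_spectra):
        peaks = []
        for i, pk in enumerate(spec.peaks):
            ppm = pk.ppm
            if spec.segment_shifts is not None and i in spec.shifted_peaks:
                ppm = ppm + spec.segment_shifts[j]
            amp = pk.amplitude
            if spec.dilution_factors is not None:
                amp = amp * spec.dilution_factors[j]
            peaks.append(PeakSpec(ppm=ppm, amplitude=amp,
                                  linewidth_hz=pk.linewidth_hz, sticks=pk.sticks))
        fid = gen_fid(peaks, acq, noise_sd=spec.noise_sd, seed=spec.seed + j)
        if spec.lb_hz > 0:
            fid = apodize_exponential(fid, spec.lb_hz)
        if spec.zero_fill_to:
            fid = zero_fill(fid, spec.zero_fill_to)
        s = fourier_transform(fid)
        if spec.phase_errors is not None:
            phi0, phi1 = spec.phase_errors[j]
            fk = np.arange(s.n_points) / (s.n_points - 1)
            s.points = s.points * np.exp(1j * np.deg2rad(phi0 + phi1 * fk))
            s.log.append("synthetic phase distortion applied")
        if spec.baseline_polys is not None:
            u = np.linspace(-1.0, 1.0, s.n_points)
            s.points = s.points + np.polyval(spec.baseline_polys[j], u)
        spectra.append(s)
    dataset = SpectraSet(spectra=spectra,
                         class_labels=[f"sample_{j + 1}" for j in range(spec.n_spectra)])
    truth = {
        "phase_errors": spec.phase_errors,
        "segment_shifts": spec.segment_shifts,
        "dilution_factors": spec.dilution_factors,
        "peaks": spec.peaks,
        "seed": spec.seed,
    }
    return dataset, truth


def gen_multiplet_trace(x: IsotopomerDistribution, entry: MetaboliteEntry, carbon: int,
                        linewidth_hz: float = 2.0, noise_sd: float = 0.0, seed: int = 0,
                        span_hz: float | None = None, n_points: int = 2048):
    """Forward-model a carbon-dimension multiplet trace from a distribution.

    Returns ``(axis_hz, trace)``; the trace is the component mixture implied
    by :func:`forward_multiplet`, convolved with a Lorentzian of the stated
    width, plus Gaussian noise.
    """
    fractions = forward_multiplet(x, entry, carbon)
    model = build_multiplet_model(entry, carbon, linewidth_hz=linewidth_hz)
    if span_hz is None:
        max_pos = max(float(np.max(np.abs(pos))) for _, pos, _ in model.components)
        span_hz = 2.0 * max_pos + 30.0 * linewidth_hz
    axis = np.linspace(-span_hz, span_hz, n_points)
    trace = np.zeros(n_points)
    for label, pos, w in model.components:
        for p, wt in zip(pos, w):
            trace += fractions[label] * wt * _lorentzian(axis, p, linewidth_hz)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + noise_sd * rng.standard_normal(n_points)
    return axis, trace


def gen_bruker_fixture(dir_path, fid: Fid, byte_order: str | None = None,
                       encoding: str | None = None) -> None:
    """Write a minimal standard-conforming Bruker 1D experiment directory.

    ``encoding='int32'`` rounds values to integers (bit-identical round
    trips therefore need integer-valued fids); ``'float64'`` is lossless.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    acq = fid.acq
    byte_order = byte_order or acq.byte_order
    encoding = encoding or acq.data_type
    if byte_order not in ("little", "big"):
        raise InputError(f"byte_order must be 'little' or 'big', got {byte_order!r}")
    if encoding not in ("int32", "float64"):
        raise InputError(f"encoding must be 'int32' or 'float64', got {encoding!r}")

    inter = np.empty(2 * len(fid), dtype=np.float64)
    inter[0::2] = fid.points.real
    inter[1::2] = fid.points.imag
    prefix = "<" if byte_order == "little" else ">"
    if encoding == "int32":
        raw = np.round(inter).astype(prefix + "i4")
    else:
        raw = inter.astype(prefix + "f8")
    (d / "fid").write_bytes(raw.tobytes())

    lines = [
        "##TITLE= Parameter file, nmlab synthetic fixture",
        "##JCAMPDX= 5.0",
        f"##$BYTORDA= {1 if byte_order == 'big' else 0}",
        f"##$DTYPA= {2 if encoding == 'float64' else 0}",
        f"##$TD= {2 * len(fid)}",
        f"##$SW_h= {acq.spectral_width_hz}",
        f"##$SFO1= {acq.spectrometer_freq_mhz}",
        f"##$O1= {acq.carrier_offset_hz}",
        f"##$GRPDLY= {acq.group_delay}",
        f"##$PULPROG= <{acq.pulse_program or 'zg30'}>",
        "##$D= (0..63)",
    ]
    delays = ["0"] * 64
    delays[1] = "4.0"
    for i in range(0, 64, 8):
        lines.append(" ".join(delays[i:i + 8]))
    lines.append("##END=")
    (d / "acqus").write_text("\n".join(lines) + "\n")

    pdata = d / "pdata" / "1"
    pdata.mkdir(parents=True, exist_ok=True)
    if acq.title:
        (pdata / "title").write_text(acq.title + "\n")
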