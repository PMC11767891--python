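"""Single-spectrum 1D processing.

Operations are pure: each takes a :class:`~nmlab.core.Fid` or
:class:`~nmlab.core.Spectrum1D` and returns a new object, appending a short
entry to the spectrum log so a processing chain is fully auditable.

Conventions
-----------
* ppm axis descends left to right; index 0 is the highest ppm.
* Phase angles are in degrees. The first-order ramp is linear in the
  normalized index ``k/(N-1)`` measured from the left (high-ppm) edge, i.e.
  the pivot sits at the left edge.
* The Bruker digital-filter group delay is compensated by a circular shift
  of the fid by the rounded delay plus a first-order frequency-domain ramp
  for the fractional remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Fid, ProcPars, Spectrum1D
from .errors import InputError, ReferencingError

__all__ = [
    "SplineBaselineSpec",
    "apodize_exponential",
    "zero_fill",
    "fourier_transform",
    "apply_phase",
    "reference_spectrum",
    "suppress_water",
    "suppress_water_conv",
    "suppress_water_poly",
    "spline_baseline",
]

#: default target ppm for each automatic referencing mode
REFERENCE_TARGETS = {"tmsp": 0.0, "water": 4.70}
#: default search windows (low, high) in ppm for each referencing mode
REFERENCE_WINDOWS = {"tmsp": (-0.5, 0.5), "water": (4.2, 5.2)}


@dataclass
class SplineBaselineSpec:
    """Anchor positions and gap limit for spline baseline correction."""

    anchor_ppms: list
    max_gap_points: int = 1000

    def __post_init__(self) -> None:
        if len(self.anchor_ppms) < 2:
            raise InputError("spline baseline needs at least 2 anchors")
        if self.max_gap_points < 2:
            raise InputError("max_gap_points must be >= 2")


def apodize_exponential(fid: Fid, lb: float) -> Fid:
    """Multiply the fid with a decaying exponential (line broadening ``lb`` Hz).

    Point ``k`` is scaled by ``exp(-pi * lb * k * dwell)``; the first point is
    unchanged. ``lb = 0`` is the identity.
    """
    if lb < 0:
        raise InputError(f"line broadening must be >= 0, got {lb}")
    k = np.arange(len(fid))
    window = np.exp(-np.pi * lb * k * fid.dwell_s)
    return fid.copy_with(fid.points * window)


def zero_fill(fid: Fid, target_n: int) -> Fid:
    """Append zeros so the fid holds exactly ``target_n`` complex points."""
    n = len(fid)
    if target_n < n:
        raise InputError(f"zero-fill target {target_n} smaller than current length {n}")
    if target_n == n:
        return fid.copy_with(fid.points)
    out = np.zeros(target_n, dtype=np.complex128)
    out[:n] = fid.points
    return fid.copy_with(out)


def fourier_transform(fid: Fid) -> Spectrum1D:
    """FFT the fid into a :class:`Spectrum1D` with a descending ppm axis.

    The frequency axis is centered on the carrier; ppm values follow from
    ``(carrier_offset_hz + f) / spectrometer_freq_mhz``.
    """
    acq = fid.acq
    x = fid.points
    n = x.size
    gd = acq.group_delay
    n0 = int(round(gd))
    frac = gd - n0
    if n0:
        x = np.roll(x, -n0)
    spec = np.fft.fft(x)
    if frac:
        # residual fractional delay -> linear phase ramp across frequency
        spec = spec * np.exp(2j * np.pi * np.fft.fftfreq(n) * frac)
    spec = np.fft.fftshift(spec)
    f = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell_s))
    ppm = (acq.carrier_offset_hz + f) / acq.spectrometer_freq_mhz
    return Spectrum1D(
        points=spec[::-1].copy(),
        ppm_axis=ppm[::-1].copy(),
        proc=ProcPars(zero_fill_size=n),
        acq=acq,
        log=[f"fourier_transform(n={n}, group_delay={gd})"],
    )


def apply_phase(spec: Spectrum1D, phi0: float, phi1: float) -> Spectrum1D:
    """Apply zero/first-order phase correction (degrees).

    Point ``k`` is multiplied by ``exp(i*pi/180*(phi0 + phi1*k/(N-1)))`` with
    ``k`` counted from the left (high-ppm) edge. Successive applications
    accumulate in the stored phase state, so the operation is a group action.
    """
    n = spec.n_points
    fk = np.arange(n) / (n - 1)
    factor = np.exp(1j * np.deg2rad(phi0 + phi1 * fk))
    out = spec.copy(points=spec.points * factor, phi0_deg=spec.phi0_deg + phi0,
                    phi1_deg=spec.phi1_deg + phi1)
    out.log.append(f"apply_phase(phi0={phi0}, phi1={phi1})")
    return out


def reference_spectrum(
    spec: Spectrum1D,
    mode: str = "tmsp",
    anchor_ppm: float | None = None,
    search_window: tuple | None = None,
) -> Spectrum1D:
    """Shift the ppm axis so the tallest real point in a window lands on target.

    ``tmsp`` targets 0.0 ppm, ``water`` 4.70 ppm, ``manual`` targets
    ``anchor_ppm``. Only the axis offset moves; data are untouched. No
    sub-point interpolation is attempted (half-point accuracy).
    """
    if mode not in ("tmsp", "water", "manual"):
        raise InputError(f"unknown reference mode {mode!r}")
    if mode == "manual":
        if anchor_ppm is None:
            raise InputError("manual referencing requires anchor_ppm")
        target = float(anchor_ppm)
        window = search_window or (target - 0.3, target + 0.3)
    else:
        target = REFERENCE_TARGETS[mode]
        window = search_window or REFERENCE_WINDOWS[mode]

    idx = spec.window_indices(window[0], window[1])
    if idx.size == 0:
        raise ReferencingError(f"search window {window} contains no points")
    seg = spec.points.real[idx]
    if np.max(seg) <= 0:
        raise ReferencingError(f"no positive maximum inside window {window}")
    peak_ppm = spec.ppm_axis[idx[np.argmax(seg)]]
    shift = target - peak_ppm
    out = spec.copy(ppm_axis=spec.ppm_axis + shift)
    out.proc.reference_mode = mode
    out.proc.reference_ppm = target
    out.log.append(f"reference_spectrum(mode={mode}, shift={shift:+.6f} ppm)")
    return out


def _kernel(window: str, width: int) -> np.ndarray:
    if window == "gauss":
        k = np.arange(width) - (width - 1) / 2.0
        sigma = max(width / 4.0, 0.5)
        ker = np.exp(-0.5 * (k / sigma) ** 2)
    elif window == "sine":
        ker = np.sin(np.pi * (np.arange(width) + 0.5) / width)
    else:
        raise InputError(f"unknown convolution window {window!r}")
    return ker / ker.sum()


def suppress_water_conv(fid: Fid, window: str = "gauss", width_points: int = 32) -> Fid:
    """Remove the on-carrier (water) component by moving-window convolution.

    The slowly varying part of the fid is estimated by convolving with a
    normalized Gaussian or sine kernel of ``width_points`` and subtracted.
    Edge weights are renormalized so a constant fid is reproduced exactly and
    therefore removed completely.
    """
    n = len(fid)
    if not (1 <= width_points < n):
        raise InputError(f"width_points must be in [1, {n}), got {width_points}")
    ker = _kernel(window, width_points)
    ones = np.ones(n)
    norm = np.convolve(ones, ker, mode="same")
    smooth = (
        np.convolve(fid.points.real, ker, mode="same")
        + 1j * np.convolve(fid.points.imag, ker, mode="same")
    ) / norm
    return fid.copy_with(fid.points - smooth)


def suppress_water_poly(fid: Fid, order: int = 4) -> Fid:
    """Remove a slow drift by subtracting a least-squares polynomial fit.

    Real and imaginary parts are fitted separately over the time axis.
    """
    n = len(fid)
    if not (0 <= order <= 10):
        raise InputError(f"polynomial order must be in [0, 10], got {order}")
    if order >= n:
        raise InputError(f"order {order} >= number of points {n}")
    t = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.polynomial.polyvander(t, order)
    coef_r, *_ = np.linalg.lstsq(V, fid.points.real, rcond=None)
    coef_i, *_ = np.linalg.lstsq(V, fid.points.imag, rcond=None)
    drift = V @ coef_r + 1j * (V @ coef_i)
    return fid.copy_with(fid.points - drift)


def suppress_water(fid: Fid, mode: str, **kwargs) -> Fid:
    """Dispatch on the configured water-suppression mode."""
    if mode == "none":
        return fid.copy_with(fid.points)
    if mode == "poly":
        return suppress_water_poly(fid, **kwargs)
    if mode == "conv_gauss":
        return suppress_water_conv(fid, window="gauss", **kwargs)
    if mode == "conv_sine":
        return suppress_water_conv(fid, window="sine", **kwargs)
    if mode == "wavelet":
        raise NotImplementedError(
            "wavelet-based water suppression is a reserved hook and not implemented"
        )
    raise InputError(f"unknown water suppression mode {mode!r}")


def _augment_anchors(idx: np.ndarray, vals: np.ndarray, max_gap: int):
    """Insert synthetic anchors on the straight line between anchors that are
    more than ``max_gap`` points apart, at spacing <= ``max_gap``."""
    out_i: list = []
    out_v: list = []
    for a in range(len(idx) - 1):
        i1, i2 = int(idx[a]), int(idx[a + 1])
        v1, v2 = float(vals[a]), float(vals[a + 1])
        out_i.append(i1)
        out_v.append(v1)
        gap = i2 - i1
        if gap > max_gap:
            n_seg = int(np.ceil(gap / max_gap))
            for k in range(1, n_seg):
                xi = int(round(i1 + k * gap / n_seg))
                out_i.append(xi)
                out_v.append(v1 + (v2 - v1) * (xi - i1) / gap)
    out_i.append(int(idx[-1]))
    out_v.append(float(vals[-1]))
    return np.asarray(out_i), np.asarray(out_v)


def spline_baseline(spec: Spectrum1D, bspec: SplineBaselineSpec):
    """Cubic-spline baseline correction with linear fill across large gaps.

    Anchor values are the median of the real part within +-2 points of each
    anchor. Anchor pairs farther apart than ``max_gap_points`` receive
    synthetic intermediate anchors on the straight line between them, which
    prevents the spline from over-correcting dense signal regions. A natural
    cubic spline through the augmented anchor set is subtracted from the real
    part.

    Returns
    -------
    (Spectrum1D, np.ndarray)
        The corrected spectrum and the subtracted baseline curve.
    """
    if len(bspec.anchor_ppms) < 2:
        raise InputError("need at least 2 anchors")
    n = spec.n_points
    idx = np.array(sorted({spec.index_of_ppm(p) for p in bspec.anchor_ppms}))
    if idx.size < 2:
        raise InputError("anchors collapse to fewer than 2 distinct points")
    r = spec.points.real
    vals = np.array([np.median(r[max(0, i - 2): min(n, i + 3)]) for i in idx])
    aug_i, aug_v = _augment_anchors(idx, vals, bspec.max_gap_points)
    cs = CubicSpline(aug_i, aug_v, bc_type="natural", extrapolate=True)
    baseline = cs(np.arange(n))
    out = spec.copy(points=(r - baseline) + 1j * spec.points.imag)
    out.log.append(
        f"spline_baseline(n_anchors={idx.size}, n_augmented={aug_i.size}, "
        f"max_gap={bspec.max_gap_points})"
    )
    return out, baseline
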