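"""Series-level pre-processing of a set of spectra on a common ppm grid.

The pipeline order is fixed: exclude -> align -> noise filter -> bucket ->
normalize -> glog -> export. Each stage logs what it did (or that it was
skipped) into the set log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Spectrum1D
from .errors import ConfigError, InputError, NmlabError, NormalizationError

__all__ = [
    "SpectraSet",
    "PreprocOptions",
    "FeatureMatrix",
    "exclude_regions",
    "segment_align",
    "noise_filter",
    "bucket_spectra",
    "normalize",
    "glog_transform",
    "run_pipeline",
]


@dataclass
class PreprocOptions:
    """All pre-processing choices; maps 1:1 to the YAML config."""

    exclude: list = field(default_factory=list)  # list of (low, high) ppm
    align_segments: list = field(default_factory=list)  # (low, high, ref_idx, max_shift)
    noise_region: tuple | None = None  # (low, high) ppm
    noise_factor: float = 4.0
    bucket_ppm: float = 0.0  # 0 disables bucketing
    bucket_mean: bool = False
    normalization: str = "none"  # none|tsa|pqn
    glog_lambda: float | None = None  # None disables glog
    export: str = ""  # ""|metaboanalyst_csv|excel
    export_path: str = ""

    def to_dict(self) -> dict:
        return {
            "exclude": [list(r) for r in self.exclude],
            "align_segments": [list(s) for s in self.align_segments],
            "noise_region": list(self.noise_region) if self.noise_region else None,
            "noise_factor": self.noise_factor,
            "bucket_ppm": self.bucket_ppm,
            "bucket_mean": self.bucket_mean,
            "normalization": self.normalization,
            "glog_lambda": self.glog_lambda,
            "export": self.export,
            "export_path": self.export_path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocOptions":
        d = dict(d)
        if d.get("noise_region"):
            d["noise_region"] = tuple(d["noise_region"])
        d["exclude"] = [tuple(r) for r in d.get("exclude", [])]
        d["align_segments"] = [tuple(s) for s in d.get("align_segments", [])]
        return cls(**d)


@dataclass
class SpectraSet:
    """Ordered spectra on identical ppm axes, with class labels and options."""

    spectra: list
    class_labels: list = field(default_factory=list)
    options: PreprocOptions = field(default_factory=PreprocOptions)
    transforms: list = field(default_factory=list)
    log: list = field(default_factory=list)
    multiplet_fits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise InputError("SpectraSet needs at least one spectrum")
        axis0 = self.spectra[0].ppm_axis
        for s in self.spectra[1:]:
            if s.ppm_axis.shape != axis0.shape or not np.array_equal(s.ppm_axis, axis0):
                raise InputError("all spectra must share an identical ppm axis")
        if not self.class_labels:
            # default the class label to the first line of the Bruker title
            self.class_labels = [
                (s.acq.title.splitlines()[0] if s.acq and s.acq.title else "")
                for s in self.spectra
            ]
        if len(self.class_labels) != len(self.spectra):
            raise InputError("class_labels must match the number of spectra")

    @property
    def ppm_axis(self) -> np.ndarray:
        return self.spectra[0].ppm_axis

    @property
    def matrix(self) -> np.ndarray:
        """samples x points view of the real parts."""
        return np.vstack([s.points.real for s in self.spectra])

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            spectra=[s.copy() for s in self.spectra],
            class_labels=list(self.class_labels),
            options=self.options,
            transforms=list(self.transforms),
            log=list(self.log),
            multiplet_fits=dict(self.multiplet_fits),
        )


@dataclass
class FeatureMatrix:
    """samples x features table with descending ppm feature labels."""

    values: np.ndarray
    feature_ppm: np.ndarray
    class_labels: list
    transforms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ppm = np.asarray(self.feature_ppm, dtype=float)
        if np.any(np.isnan(self.values)):
            raise InputError("feature matrix contains NaN")
        if self.feature_ppm.size >= 2 and not np.all(np.diff(self.feature_ppm) < 0):
            raise InputError("feature_ppm must be descending")

    def copy(self, **changes) -> "FeatureMatrix":
        base = dict(
            values=self.values.copy(),
            feature_ppm=self.feature_ppm.copy(),
            class_labels=list(self.class_labels),
            transforms=list(self.transforms),
        )
        base.update(changes)
        return FeatureMatrix(**base)


def _check_region(region) -> tuple:
    low, high = float(region[0]), float(region[1])
    if low >= high:
        raise InputError(f"malformed ppm interval ({low}, {high}): low must be < high")
    return low, high


def exclude_regions(dataset: SpectraSet, regions) -> SpectraSet:
    """Zero all points inside the given ppm intervals, in every spectrum.

    Idempotent; overlapping regions zero their union. Zeroed features are
    dropped later at export.
    """
    out = dataset.copy()
    if not regions:
        out.log.append("exclude_regions: no regions")
        return out
    axis = out.ppm_axis
    mask = np.zeros(axis.size, dtype=bool)
    for region in regions:
        low, high = _check_region(region)
        mask |= (axis >= low) & (axis < high)
    for s in out.spectra:
        s.points[mask] = 0.0
    out.log.append(f"exclude_regions: zeroed {int(mask.sum())} points in {len(regions)} regions")
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _shift_segment(seg: np.ndarray, s: int) -> np.ndarray:
    """Move segment content by ``s`` points; vacated positions get the mean
    of the segment's two edge values (avoids step artifacts)."""
    out = np.empty_like(seg)
    fill = 0.5 * (seg[0] + seg[-1])
    if s == 0:
        return seg.copy()
    if s > 0:
        out[s:] = seg[:-s]
        out[:s] = fill
    else:
        out[:s] = seg[-s:]
        out[s:] = fill
    return out


def segment_align(dataset: SpectraSet, segment, ref_index: int, max_shift: int | None = None,
                  noise_floor: float = 0.0):
    """Align one ppm segment of every spectrum to a reference spectrum.

    For each non-reference spectrum the integer shift in
    ``[-max_shift, +max_shift]`` maximizing the Pearson correlation with the
    reference segment is applied (content moved, vacated positions filled
    with the segment-edge mean). Ties break toward the smallest ``|s|``,
    then toward negative ``s``. If the reference segment carries no signal
    above ``noise_floor``, nothing is aligned.

    Returns
    -------
    (SpectraSet, list[int], list[float], list[float])
        Aligned set, per-spectrum shifts, correlations before, after.
    """
    low, high = _check_region(segment)
    out = dataset.copy()
    idx = out.spectra[0].window_indices(low, high)
    if idx.size < 8:
        raise InputError(f"segment ({low}, {high}) covers only {idx.size} points (< 8)")
    if not (0 <= ref_index < len(out.spectra)):
        raise InputError(f"ref_index {ref_index} out of range")
    if max_shift is None:
        max_shift = idx.size // 4

    ref_seg = out.spectra[ref_index].points.real[idx]
    n_spec = len(out.spectra)
    shifts = [0] * n_spec
    corr_before = [1.0] * n_spec
    corr_after = [1.0] * n_spec

    if np.max(np.abs(ref_seg)) <= noise_floor:
        out.log.append(f"segment_align({low},{high}): no reference signal, skipped")
        return out, shifts, corr_before, corr_after

    for j, s in enumerate(out.spectra):
        if j == ref_index:
            continue
        seg = s.points.real[idx]
        corr_before[j] = _pearson(seg, ref_seg)
        best_s, best_r = 0, -np.inf
        for cand in range(-max_shift, max_shift + 1):
            # correlate on the overlap only so fill values never bias the score
            if cand >= 0:
                r = _pearson(seg[: idx.size - cand] if cand else seg,
                             ref_seg[cand:] if cand else ref_seg)
            else:
                r = _pearson(seg[-cand:], ref_seg[:cand])
            better = r > best_r + 1e-15
            tie = abs(r - best_r) <= 1e-15
            if better or (tie and (abs(cand) < abs(best_s) or
                                   (abs(cand) == abs(best_s) and cand < best_s))):
                best_s, best_r = cand, r
        shifted = _shift_segment(seg, best_s)
        shifts[j] = best_s
        corr_after[j] = _pearson(shifted, ref_seg)
        full = s.points.real.copy()
        full[idx] = shifted
        s.points = full + 1j * s.points.imag
    out.log.append(f"segment_align({low},{high}): shifts={shifts}")
    return out, shifts, corr_before, corr_after


def noise_filter(dataset: SpectraSet, noise_region, k: float):
    """Zero every point whose across-spectra maximum is below ``k * sigma``.

    ``sigma`` is the standard deviation of the real points in
    ``noise_region`` pooled over all spectra. ``k = 0`` is the identity.
    """
    low, high = _check_region(noise_region)
    out = dataset.copy()
    idx = out.spectra[0].window_indices(low, high)
    if idx.size == 0:
        raise InputError(f"noise region ({low}, {high}) contains no points")
    pooled = np.concatenate([s.points.real[idx] for s in out.spectra])
    sigma = float(pooled.std())
    if k <= 0:
        out.log.append("noise_filter: k<=0, identity")
        return out
    col_max = out.matrix.max(axis=0)
    zap = col_max < k * sigma
    for s in out.spectra:
        s.points[zap] = 0.0
    out.log.append(f"noise_filter: sigma={sigma:.4g}, k={k}, zeroed {int(zap.sum())} points")
    return out


def bucket_spectra(dataset: SpectraSet, width_ppm: float, aggregate_mean: bool = False) -> FeatureMatrix:
    """Aggregate points into contiguous ppm bins of fixed width.

    Bins are half-open, laid out from the high-ppm end; the bucket value is
    the sum of real points in the bin (total signal conserved) or the mean
    when ``aggregate_mean`` is set; labels are the bin centers.
    """
    axis = dataset.ppm_axis
    spacing = dataset.spectra[0].ppm_spacing
    if width_ppm < spacing:
        raise InputError(f"bucket width {width_ppm} smaller than point spacing {spacing:.3g}")
    high = axis[0]
    bins = np.floor((high - axis) / width_ppm + 1e-12).astype(int)
    n_buckets = int(bins.max()) + 1
    mat = dataset.matrix
    values = np.zeros((mat.shape[0], n_buckets))
    np.add.at(values.T, bins, mat.T)
    if aggregate_mean:
        counts = np.bincount(bins, minlength=n_buckets)
        values = values / counts
    centers = high - (np.arange(n_buckets) + 0.5) * width_ppm
    return FeatureMatrix(values=values, feature_ppm=centers, class_labels=list(dataset.class_labels))


def raw_feature_matrix(dataset: SpectraSet) -> FeatureMatrix:
    """Identity featurization: one feature per spectral point."""
    return FeatureMatrix(
        values=dataset.matrix.copy(),
        feature_ppm=dataset.ppm_axis.copy(),
        class_labels=list(dataset.class_labels),
    )


def normalize(matrix: FeatureMatrix, mode: str, tsa_first: bool = True):
    """Scale samples by total-sum (tsa) or probabilistic quotient (pqn).

    tsa divides each sample by its feature total and multiplies by the
    cohort-mean total. pqn optionally applies tsa first, takes the
    feature-wise median sample as reference, and divides each sample by the
    median of its feature-wise quotients against the reference.

    Returns
    -------
    (FeatureMatrix, np.ndarray)
        Normalized matrix and the overall per-sample divisors.
    """
    if mode not in ("tsa", "pqn"):
        raise InputError(f"unknown normalization mode {mode!r}")
    vals = matrix.values.copy()
    totals = vals.sum(axis=1)
    for j, t in enumerate(totals):
        if t <= 0:
            name = matrix.class_labels[j] or f"sample_{j + 1}"
            raise NormalizationError(f"sample {j + 1} ({name}) has non-positive total {t}")
    mean_total = totals.mean()
    factors = np.ones(vals.shape[0])
    if mode == "tsa" or (mode == "pqn" and tsa_first):
        tsa_factors = totals / mean_total
        vals = vals / tsa_factors[:, None]
        factors *= tsa_factors
    if mode == "pqn":
        ref = np.median(vals, axis=0)
        pos = ref > 0
        if not pos.any():
            raise NormalizationError("pqn reference spectrum has no positive features")
        quotients = vals[:, pos] / ref[pos]
        pqn_factors = np.median(quotients, axis=1)
        vals = vals / pqn_factors[:, None]
        factors *= pqn_factors
    out = matrix.copy(values=vals)
    out.transforms.append(mode)
    return out, factors


def glog_transform(matrix: FeatureMatrix, lam: float) -> FeatureMatrix:
    """Variance-stabilizing generalized log: ``y = ln(x + sqrt(x^2 + lambda))``.

    With ``lambda = 0`` this is ``ln(2x)`` and requires strictly positive data.
    """
    if lam < 0:
        raise InputError(f"glog lambda must be >= 0, got {lam}")
    x = matrix.values
    if lam == 0 and np.any(x <= 0):
        raise InputError("glog with lambda=0 requires all values > 0")
    if lam == 0:
        y = np.log(2 * x)
    else:
        root = np.sqrt(x * x + lam)
        # x + root cancels catastrophically for x < 0 with small lambda; use
        # the conjugate form ln(lambda) - ln(root - x) on that branch
        y = np.empty_like(x, dtype=float)
        pos = x >= 0
        y[pos] = np.log(x[pos] + root[pos])
        y[~pos] = np.log(lam) - np.log(root[~pos] - x[~pos])
    out = matrix.copy(values=y)
    out.transforms.append("glog")
    return out


def default_glog_lambda(matrix: FeatureMatrix) -> float:
    m = float(np.max(np.abs(matrix.values))) if matrix.values.size else 0.0
    return 1e-6 * m * m


def run_pipeline(dataset: SpectraSet, opts: PreprocOptions) -> FeatureMatrix:
    """Run the full fixed-order pre-processing chain and return the matrix.

    Stage order: exclude -> align -> noise filter -> bucket -> normalize ->
    glog -> export. Skipped stages are logged as skipped; stage errors are
    re-raised with the stage name attached.
    """
    excluded_mask = None
    if opts.exclude and opts.align_segments:
        axis = dataset.ppm_axis
        excluded_mask = np.zeros(axis.size, dtype=bool)
        for region in opts.exclude:
            low, high = _check_region(region)
            excluded_mask |= (axis >= low) & (axis < high)
        for seg in opts.align_segments:
            low, high = _check_region(seg[:2])
            if np.any(excluded_mask & (axis >= low) & (axis < high)):
                raise ConfigError(
                    f"align segment ({low}, {high}) overlaps an excluded region"
                )

    ds = dataset

    def run_stage(name, fn):
        try:
            return fn()
        except NmlabError as e:
            raise type(e)(f"[stage {name}] {e}") from e

    if opts.exclude:
        ds = run_stage("exclude", lambda: exclude_regions(ds, opts.exclude))
    else:
        ds.log.append("exclude: skipped")

    if opts.align_segments:
        for seg in opts.align_segments:
            low, high = seg[0], seg[1]
            ref_idx = int(seg[2]) if len(seg) > 2 else 0
            max_shift = int(seg[3]) if len(seg) > 3 else None
            ds, _, _, _ = run_stage(
                "align", lambda s=(low, high), r=ref_idx, m=max_shift: segment_align(ds, s, r, m)
            )
    else:
        ds.log.append("align: skipped")

    if opts.noise_region:
        ds = run_stage("noise_filter", lambda: noise_filter(ds, opts.noise_region, opts.noise_factor))
    else:
        ds.log.append("noise_filter: skipped")

    if opts.bucket_ppm > 0:
        matrix = run_stage("bucket", lambda: bucket_spectra(ds, opts.bucket_ppm,
                                                            aggregate_mean=opts.bucket_mean))
        ds.log.append(f"bucket: width={opts.bucket_ppm}")
    else:
        matrix = raw_feature_matrix(ds)
        ds.log.append("bucket: skipped")

    if opts.normalization in ("tsa", "pqn"):
        matrix, factors = run_stage("normalize", lambda: normalize(matrix, opts.normalization))
        ds.log.append(f"normalize({opts.normalization}): factors={np.round(factors, 6).tolist()}")
    else:
        ds.log.append("normalize: skipped")

    if opts.glog_lambda is not None:
        if "glog" in dataset.transforms:
            ds.log.append("glog: already applied, skipped")
        else:
            matrix = run_stage("glog", lambda: glog_transform(matrix, opts.glog_lambda))
            dataset.transforms.append("glog")
            ds.log.append(f"glog: lambda={opts.glog_lambda}")
    else:
        ds.log.append("glog: skipped")

    if opts.export and opts.export_path:
        from .bruker_io import export_statistics  # avoid import cycle

        run_stage("export", lambda: export_statistics(matrix, opts.export, opts.export_path))
        ds.log.append(f"export: {opts.export} -> {opts.export_path}")
    else:
        ds.log.append("export: skipped")

    dataset.log.extend(x for x in ds.log if x not in dataset.log)
    return matrix
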