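"""Reading and writing Bruker-style experiment directories, the native
dataset container, and statistics exports.

Supported Bruker dialect: 1D experiments with ``fid`` encoded as int32 or
float64 (``DTYPA``), either endianness (``BYTORDA``), parameters in
JCAMP-DX-style ``acqus``, processed data under ``pdata/1`` (``1r``/``1i``
as int32 with the ``NC_proc`` scaling convention).

The native dataset format is a zip container holding a JSON manifest
(version string required) plus one ``.npy`` blob per array. It is
deliberately self-contained and versioned; loading an unknown version
raises :class:`~nmlab.errors.FormatError`.
"""

from __future__ import annotations

import io
import json
import re
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AcqPars, Fid, ProcPars, Spectrum1D
from .errors import FormatError, InputError

__all__ = [
    "parse_param_file",
    "read_bruker",
    "write_bruker",
    "read_bruker_proc",
    "save_dataset",
    "load_dataset",
    "export_statistics",
]

NATIVE_VERSION = "1"

_PARAM_RE = re.compile(r"^##\$?(?P<key>[^=]+)=\s*(?P<val>.*)$")
_ARRAY_HEADER_RE = re.compile(r"^\(\d+\.\.\d+\)\s*(?P<rest>.*)$")


def _convert_token(tok: str):
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        pass
    return tok.strip("<>")


def parse_param_file(text: str) -> dict:
    """Parse JCAMP-DX-style ``##$KEY= value`` parameter text into a dict.

    Scalars become int/float where possible; ``<bracketed>`` strings are
    unwrapped; array values declared as ``(0..N)`` and continued over
    multiple lines are joined into lists. The function is total: any text
    yields a dict without raising, unknown content is preserved verbatim.
    """
    params: dict = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        m = _PARAM_RE.match(lines[i])
        if not m:
            i += 1
            continue
        key = m.group("key").strip()
        val = m.group("val").strip()
        am = _ARRAY_HEADER_RE.match(val)
        if am:
            toks = am.group("rest").split()
            i += 1
            while i < len(lines) and not lines[i].startswith("##"):
                toks.extend(lines[i].split())
                i += 1
            params[key] = [_convert_token(t) for t in toks]
            continue
        params[key] = _convert_token(val) if val else ""
        i += 1
    return params


def _fid_dtype(byte_order: str, data_type: str) -> np.dtype:
    prefix = "<" if byte_order == "little" else ">"
    return np.dtype(prefix + ("i4" if data_type == "int32" else "f8"))


def read_bruker(dir_path) -> tuple[Fid, AcqPars]:
    """Read a Bruker 1D experiment directory into a :class:`Fid`.

    Requires ``fid`` and ``acqus``; ``pdata/1/title`` is optional metadata.
    Raises :class:`InputError` naming any missing mandatory file and
    :class:`FormatError` for undecodable binary content.
    """
    d = Path(dir_path)
    fid_path = d / "fid"
    acqus_path = d / "acqus"
    for p in (fid_path, acqus_path):
        if not p.is_file():
            raise InputError(f"missing required file: {p}")

    params = parse_param_file(acqus_path.read_text())
    try:
        sw_h = float(params["SW_h"])
        sfo1 = float(params["SFO1"])
        td = int(params["TD"])
    except KeyError as e:
        raise FormatError(f"acqus lacks mandatory parameter {e}") from None
    byte_order = "big" if int(params.get("BYTORDA", 0)) == 1 else "little"
    data_type = "float64" if int(params.get("DTYPA", 0)) == 2 else "int32"

    raw = fid_path.read_bytes()
    dtype = _fid_dtype(byte_order, data_type)
    if len(raw) % dtype.itemsize:
        raise FormatError(f"fid size {len(raw)} not a multiple of item size {dtype.itemsize}")
    vals = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if vals.size % 2:
        raise FormatError(f"fid holds an odd number of values ({vals.size})")
    points = vals[0::2] + 1j * vals[1::2]
    if td and td // 2 != points.size:
        # acqus TD counts real+imag values; trust the binary, note mismatch
        pass

    title = ""
    title_path = d / "pdata" / "1" / "title"
    if title_path.is_file():
        title = title_path.read_text().strip()

    acq = AcqPars(
        spectral_width_hz=sw_h,
        spectrometer_freq_mhz=sfo1,
        n_points_td=points.size,
        carrier_offset_hz=float(params.get("O1", 0.0)),
        group_delay=max(float(params.get("GRPDLY", 0.0)), 0.0),
        pulse_program=str(params.get("PULPROG", "")),
        byte_order=byte_order,
        int_size=4,
        data_type=data_type,
        title=title,
    )
    return Fid(points=points, acq=acq), acq


def write_bruker(spec: Spectrum1D, dir_path) -> None:
    """Export a processed spectrum as Bruker ``pdata/1/1r`` (and ``1i``).

    Data are stored as little-endian int32 scaled by ``2**NC_proc`` so the
    largest value uses at least 28 bits; ``procs`` records ``SI``,
    ``NC_proc`` and the axis parameters needed for read-back.
    """
    d = Path(dir_path) / "pdata" / "1"
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise InputError(f"cannot create output directory {d}: {e}") from e

    def quantize(vals: np.ndarray):
        m = float(np.max(np.abs(vals))) if vals.size else 0.0
        if m == 0.0:
            return np.zeros(vals.size, dtype="<i4"), 0
        nc = int(np.ceil(np.log2(m / (2 ** 29 - 1))))
        return np.round(vals / 2.0 ** nc).astype("<i4"), nc

    ints_r, nc = quantize(spec.points.real)
    (d / "1r").write_bytes(ints_r.tobytes())
    has_imag = bool(np.any(spec.points.imag))
    if has_imag:
        scaled = np.round(spec.points.imag / 2.0 ** nc)
        (d / "1i").write_bytes(scaled.astype("<i4").tobytes())

    sf = spec.acq.spectrometer_freq_mhz if spec.acq else 1.0
    sw_p = (spec.ppm_axis[0] - spec.ppm_axis[-1]) * sf * spec.n_points / max(spec.n_points - 1, 1)
    lines = [
        "##TITLE= Parameter file, nmlab",
        "##JCAMPDX= 5.0",
        f"##$SI= {spec.n_points}",
        f"##$NC_proc= {nc}",
        "##$BYTORDP= 0",
        "##$DTYPP= 0",
        f"##$SF= {sf}",
        f"##$SW_p= {sw_p}",
        f"##$OFFSET= {spec.ppm_axis[0]}",
        f"##$PHC0= {spec.phi0_deg}",
        f"##$PHC1= {spec.phi1_deg}",
        "##END=",
    ]
    (d / "procs").write_text("\n".join(lines) + "\n")


def read_bruker_proc(dir_path) -> Spectrum1D:
    """Read processed Bruker data (``pdata/1/1r``/``1i`` + ``procs``) back."""
    d = Path(dir_path) / "pdata" / "1"
    procs_path = d / "procs"
    r_path = d / "1r"
    for p in (procs_path, r_path):
        if not p.is_file():
            raise InputError(f"missing required file: {p}")
    params = parse_param_file(procs_path.read_text())
    si = int(params["SI"])
    nc = int(params.get("NC_proc", 0))
    prefix = "<" if int(params.get("BYTORDP", 0)) == 0 else ">"
    vals_r = np.frombuffer(r_path.read_bytes(), dtype=prefix + "i4").astype(np.float64)
    if vals_r.size != si:
        raise FormatError(f"1r holds {vals_r.size} values, procs declares SI={si}")
    scale = 2.0 ** nc
    real = vals_r * scale
    imag = np.zeros_like(real)
    i_path = d / "1i"
    if i_path.is_file():
        imag = np.frombuffer(i_path.read_bytes(), dtype=prefix + "i4").astype(np.float64) * scale
    sf = float(params.get("SF", 1.0))
    sw_p = float(params.get("SW_p", 1.0))
    offset = float(params.get("OFFSET", 0.0))
    step = sw_p / sf / si
    ppm = offset - step * np.arange(si)
    return Spectrum1D(
        points=real + 1j * imag,
        ppm_axis=ppm,
        phi0_deg=float(params.get("PHC0", 0.0)),
        phi1_deg=float(params.get("PHC1", 0.0)),
    )


# ---------------------------------------------------------------------------
# native dataset container


def _np_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def _np_from(z: zipfile.ZipFile, name: str) -> np.ndarray:
    return np.load(io.BytesIO(z.read(name)))


def save_dataset(dataset, path) -> None:
    """Save a :class:`~nmlab.preprocess.SpectraSet` to the native container."""
    from .preprocess import SpectraSet  # local import avoids a cycle

    if not isinstance(dataset, SpectraSet):
        raise InputError("save_dataset expects a SpectraSet")
    manifest = {
        "version": NATIVE_VERSION,
        "n_spectra": len(dataset.spectra),
        "class_labels": list(dataset.class_labels),
        "transforms": list(dataset.transforms),
        "log": list(dataset.log),
        "options": dataset.options.to_dict(),
        "multiplet_fits": dataset.multiplet_fits,
        "spectra": [],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as z:
        for i, s in enumerate(dataset.spectra):
            manifest["spectra"].append(
                {
                    "phi0_deg": s.phi0_deg,
                    "phi1_deg": s.phi1_deg,
                    "proc": s.proc.to_dict(),
                    "acq": s.acq.to_dict() if s.acq else None,
                    "log": list(s.log),
                }
            )
            z.writestr(f"points_{i}.npy", _np_bytes(s.points))
        z.writestr("ppm.npy", _np_bytes(dataset.spectra[0].ppm_axis))
        z.writestr("manifest.json", json.dumps(manifest, indent=1))


def load_dataset(path):
    """Load a native container saved by :func:`save_dataset`."""
    from .preprocess import PreprocOptions, SpectraSet

    try:
        with zipfile.ZipFile(path) as z:
            manifest = json.loads(z.read("manifest.json"))
            version = manifest.get("version")
            if version != NATIVE_VERSION:
                raise FormatError(
                    f"unsupported dataset version {version!r} (expected {NATIVE_VERSION!r})"
                )
            ppm = _np_from(z, "ppm.npy")
            spectra = []
            for i, meta in enumerate(manifest["spectra"]):
                spectra.append(
                    Spectrum1D(
                        points=_np_from(z, f"points_{i}.npy"),
                        ppm_axis=ppm.copy(),
                        phi0_deg=meta["phi0_deg"],
                        phi1_deg=meta["phi1_deg"],
                        proc=ProcPars.from_dict(meta["proc"]),
                        acq=AcqPars.from_dict(meta["acq"]) if meta["acq"] else None,
                        log=list(meta["log"]),
                    )
                )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as e:
        raise FormatError(f"not a valid nmlab dataset: {e}") from e
    return SpectraSet(
        spectra=spectra,
        class_labels=list(manifest["class_labels"]),
        options=PreprocOptions.from_dict(manifest["options"]),
        transforms=list(manifest["transforms"]),
        log=list(manifest["log"]),
        multiplet_fits=manifest.get("multiplet_fits", {}),
    )


# ---------------------------------------------------------------------------
# statistics export


def _matrix_frame(matrix) -> pd.DataFrame:
    """Drop all-zero (excluded) feature columns and build the export table."""
    values = np.asarray(matrix.values, dtype=float)
    if values.size == 0:
        raise InputError("cannot export an empty matrix")
    keep = ~np.all(values == 0.0, axis=0)
    labels = [f"{p:.4f}" for p in np.asarray(matrix.feature_ppm)[keep]]
    df = pd.DataFrame(values[:, keep], columns=labels)
    df.insert(0, "Class", list(matrix.class_labels))
    df.insert(0, "Sample", [f"sample_{i + 1}" for i in range(values.shape[0])])
    return df


def export_statistics(matrix, fmt: str, path, multiplet_sheets: dict | None = None) -> None:
    """Export a feature matrix for statistical analysis.

    ``metaboanalyst_csv`` writes a samples-in-rows CSV whose header is
    ``Sample,Class,<ppm labels>`` with ppm labels at 4 decimals, descending.
    ``excel`` mirrors the table in a workbook and adds one sheet per entry
    of ``multiplet_sheets`` (mapping sheet name -> DataFrame-able mapping).
    All-zero feature columns (excluded regions) are dropped.
    """
    df = _matrix_frame(matrix)
    if fmt == "metaboanalyst_csv":
        df.to_csv(path, index=False)
    elif fmt == "excel":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            df.to_excel(writer, sheet_name="matrix", index=False)
            for name, sheet in (multiplet_sheets or {}).items():
                pd.DataFrame(sheet).to_excel(writer, sheet_name=str(name)[:31], index=False)
    else:
        raise InputError(f"unknown export format {fmt!r}")
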