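"""HSQC multiplet analysis on a 1D carbon-dimension trace.

The computational core of tracer-HSQC analysis: a metabolite library holds
per-carbon chemical shifts and carbon-carbon scalar couplings (JCC); the
coupling network of a carbon fixes which multiplet components can appear
(singlet for no labelled neighbor, doublets ``d1``/``d2`` for one labelled
neighbor, doublet-of-doublets ``dd`` for two); peak positions are predicted
from the couplings and the component amplitudes are fitted by separable
nonlinear least squares, yielding the percentage contribution of each
component and a coefficient-of-determination quality score with a
green/amber/red flag.

Library files (``.mlinfo``) are line-oriented text::

    # comment
    metabolite: lactate
    carbons: 3
    carbon: 1 - 183.3        # index, h_ppm ('-' = unprotonated), c_ppm
    carbon: 2 4.10 71.3
    carbon: 3 1.31 22.7
    jcc: 2 3 37.0            # carbon i, carbon j, coupling in Hz
    chain: 1-2 2-3           # optional; defaults to the linear chain
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize, nnls

from .errors import InputError, PickFailureError, SchemaError

__all__ = [
    "MetaboliteEntry",
    "MultipletModel",
    "MultipletFit",
    "PickResult",
    "load_mlinfo",
    "builtin_library_path",
    "build_multiplet_model",
    "autopick_peaks",
    "fit_multiplet",
    "quality_flag",
]


@dataclass
class MetaboliteEntry:
    """One metabolite: shifts per carbon plus the JCC coupling map."""

    name: str
    n_carbons: int
    shifts: dict  # carbon index (1-based) -> (h_ppm, c_ppm) or None
    jcc: dict = field(default_factory=dict)  # (i, j) i<j -> Hz
    chain: list = field(default_factory=list)  # neighbor pairs

    def __post_init__(self) -> None:
        for (i, j), v in self.jcc.items():
            if not v > 0:
                raise InputError(f"coupling J({i},{j}) must be > 0, got {v}")
        if not self.chain:
            self.chain = [(i, i + 1) for i in range(1, self.n_carbons)]

    def neighbors(self, carbon: int) -> list:
        out = [j for (i, j) in self.chain if i == carbon]
        out += [i for (i, j) in self.chain if j == carbon]
        return sorted(out)

    def coupling(self, i: int, j: int):
        return self.jcc.get((min(i, j), max(i, j)))

    def coupled_neighbors(self, carbon: int) -> list:
        """Neighbors with a known JCC, sorted by carbon index."""
        return [j for j in self.neighbors(carbon) if self.coupling(carbon, j) is not None]

    def observable(self, carbon: int) -> bool:
        return self.shifts.get(carbon) is not None


@dataclass
class MultipletModel:
    """Stick model of one carbon's multiplet."""

    carbon_index: int
    components: list  # (label, positions_hz ndarray, weights ndarray)
    linewidth_hz: float = 2.0
    center_hz: float = 0.0
    couplings: list = field(default_factory=list)  # J values (Hz) used

    def __post_init__(self) -> None:
        for label, pos, w in self.components:
            w = np.asarray(w, float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise InputError(f"stick weights of component {label!r} must sum to 1")

    @property
    def labels(self) -> list:
        return [c[0] for c in self.components]

    def min_coupling_hz(self):
        if self.couplings:
            return min(self.couplings)
        spans = [2 * np.min(np.abs(pos[np.abs(pos) > 0]))
                 for _, pos, _ in self.components if np.any(np.abs(pos) > 0)]
        return min(spans) if spans else None


@dataclass
class MultipletFit:
    """Result of a multiplet line-shape fit."""

    fractions: dict
    r2: float
    fitted_linewidth_hz: float
    fitted_center_hz: float
    flag: str
    diagnostics: dict = field(default_factory=dict)


def builtin_library_path(name: str) -> Path:
    """Path of a library file shipped with the package."""
    p = Path(__file__).parent / "library" / f"{name}.mlinfo"
    if not p.is_file():
        raise InputError(f"no builtin library entry named {name!r}")
    return p


def load_mlinfo(path) -> MetaboliteEntry:
    """Parse an ``.mlinfo`` metabolite library file."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"library file not found: {p}")
    name = None
    n_carbons = None
    shifts: dict = {}
    jcc: dict = {}
    chain: list = []
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise SchemaError(f"{p.name}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, val = line.partition(":")
        key = key.strip().lower()
        toks = val.split()
        try:
            if key == "metabolite":
                name = val.strip()
            elif key == "carbons":
                n_carbons = int(toks[0])
            elif key == "carbon":
                idx = int(toks[0])
                if toks[1] == "-":
                    shifts[idx] = None
                else:
                    shifts[idx] = (float(toks[1]), float(toks[2]))
            elif key == "jcc":
                i, j = int(toks[0]), int(toks[1])
                jcc[(min(i, j), max(i, j))] = float(toks[2])
            elif key == "chain":
                for pair in toks:
                    a, _, b = pair.partition("-")
                    chain.append((int(a), int(b)))
            else:
                raise SchemaError(f"{p.name}:{lineno}: unknown key {key!r}")
        except (ValueError, IndexError) as e:
            raise SchemaError(f"{p.name}:{lineno}: malformed line {raw!r} ({e})") from e
    missing = [k for k, v in (("metabolite", name), ("carbons", n_carbons)) if v is None]
    if n_carbons is not None:
        missing += [f"carbon {i}" for i in range(1, n_carbons + 1) if i not in shifts]
    if missing:
        raise SchemaError(f"{p.name}: missing mandatory keys: {', '.join(missing)}")
    return MetaboliteEntry(name=name, n_carbons=n_carbons, shifts=shifts, jcc=jcc, chain=chain)


def neighbor_pattern_components(entry: MetaboliteEntry, carbon: int) -> list:
    """Component labels in canonical order for a carbon's coupling topology.

    Returns a list of ``(label, labelled_neighbor_tuple)`` where the tuple
    holds the carbons that are 13C-labelled in that component.
    """
    nb = entry.coupled_neighbors(carbon)
    if len(nb) == 0:
        return [("s", ())]
    if len(nb) == 1:
        return [("s", ()), ("d1", (nb[0],))]
    if len(nb) == 2:
        return [("s", ()), ("d1", (nb[0],)), ("d2", (nb[1],)), ("dd", (nb[0], nb[1]))]
    raise InputError(f"carbon {carbon} has {len(nb)} coupled neighbors; at most 2 supported")


def build_multiplet_model(entry: MetaboliteEntry, carbon: int,
                          linewidth_hz: float = 2.0) -> MultipletModel:
    """Enumerate multiplet components from the labelled-neighbor patterns."""
    if not entry.observable(carbon):
        raise InputError(f"carbon {carbon} of {entry.name} is unobservable (no HSQC shift)")
    comps = []
    for label, labelled in neighbor_pattern_components(entry, carbon):
        if not labelled:
            pos = np.array([0.0])
        elif len(labelled) == 1:
            j = entry.coupling(carbon, labelled[0])
            pos = np.array([-j / 2.0, j / 2.0])
        else:
            j1 = entry.coupling(carbon, labelled[0])
            j2 = entry.coupling(carbon, labelled[1])
            pos = np.array([-j1 / 2 - j2 / 2, -j1 / 2 + j2 / 2, j1 / 2 - j2 / 2, j1 / 2 + j2 / 2])
        comps.append((label, pos, np.full(pos.size, 1.0 / pos.size)))
    js = [entry.coupling(carbon, j) for j in entry.coupled_neighbors(carbon)]
    return MultipletModel(carbon_index=carbon, components=comps,
                          linewidth_hz=linewidth_hz, couplings=js)


@dataclass
class PickResult:
    positions_hz: list
    displacements_hz: list
    center_hz: float


def autopick_peaks(trace: np.ndarray, axis_hz: np.ndarray, model: MultipletModel) -> PickResult:
    """Locate a local maximum near every predicted stick position.

    The search tolerance is ``max(0.25 * J_min, 2 points)``. Failing to find
    a strict local maximum for more than half the sticks raises
    :class:`PickFailureError` (maps to a red quality flag downstream).
    """
    trace = np.asarray(trace, float)
    axis_hz = np.asarray(axis_hz, float)
    spacing = abs(axis_hz[1] - axis_hz[0])
    jmin = model.min_coupling_hz()
    tol = max(0.25 * jmin, 2 * spacing) if jmin else max(2 * spacing, 2.0)

    sticks = []
    for _, pos, w in model.components:
        for p, wt in zip(pos, w):
            sticks.append((p, wt))

    positions, displacements, weights = [], [], []
    failures = 0
    for p, wt in sticks:
        target = model.center_hz + p
        sel = np.nonzero(np.abs(axis_hz - target) <= tol)[0]
        found = None
        if sel.size:
            local = sel[np.argmax(trace[sel])]
            if 0 < local < trace.size - 1 and trace[local] > trace[local - 1] \
                    and trace[local] > trace[local + 1]:
                found = axis_hz[local]
        if found is None:
            failures += 1
        else:
            positions.append(float(found))
            displacements.append(float(found - target))
            weights.append(wt)
    if failures > len(sticks) / 2:
        raise PickFailureError(
            f"no local maximum for {failures}/{len(sticks)} predicted sticks"
        )
    w = np.asarray(weights)
    center = model.center_hz + float(np.sum(w * np.asarray(displacements)) / w.sum())
    return PickResult(positions_hz=positions, displacements_hz=displacements, center_hz=center)


def _lorentzian(x: np.ndarray, x0: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return (hw / np.pi) / ((x - x0) ** 2 + hw ** 2)


def component_shapes(axis_hz: np.ndarray, model: MultipletModel, linewidth_hz: float,
                     center_hz: float) -> np.ndarray:
    """Design matrix: one unit-area multiplet shape per component."""
    cols = []
    for _, pos, w in model.components:
        shape = np.zeros_like(axis_hz, dtype=float)
        for p, wt in zip(pos, w):
            shape += wt * _lorentzian(axis_hz, center_hz + p, linewidth_hz)
        cols.append(shape)
    return np.column_stack(cols)


def fit_multiplet(trace: np.ndarray, axis_hz: np.ndarray, model: MultipletModel) -> MultipletFit:
    """Fit component amplitudes, shared linewidth and center to a trace.

    Amplitudes are solved by non-negative least squares for each candidate
    (linewidth, center); the two nonlinear parameters are refined with
    Powell from several deterministic restarts. Never raises on a bad fit:
    a hopeless trace comes back with a red flag and diagnostics.
    """
    trace = np.asarray(trace, float)
    axis_hz = np.asarray(axis_hz, float)

    center0 = model.center_hz
    try:
        center0 = autopick_peaks(trace, axis_hz, model).center_hz
        picked = True
    except PickFailureError:
        picked = False

    def rss_for(params):
        lw, c = params
        if lw <= 0:
            # large finite penalty keeps Powell's parabolic steps well defined
            return 1e300 * (1.0 - lw), None
        A = component_shapes(axis_hz, model, lw, c)
        amps, rnorm = nnls(A, trace)
        return rnorm ** 2, amps

    best = None
    for lw0 in (model.linewidth_hz * f for f in (0.5, 1.0, 2.0)):
        res = minimize(
            lambda p: rss_for(p)[0],
            x0=np.array([lw0, center0]),
            method="Powell",
            options={"xtol": 1e-6, "ftol": 1e-9, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    lw, center = float(abs(best.x[0])), float(best.x[1])
    rss, amps = rss_for((lw, center))
    tss = float(((trace - trace.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = float(min(max(r2, 0.0), 1.0))

    total = amps.sum()
    if total > 0:
        fractions = {lbl: float(a / total) for lbl, a in zip(model.labels, amps)}
    else:
        fractions = {lbl: 1.0 / len(model.labels) for lbl in model.labels}
    flag = quality_flag(r2)
    if total == 0:
        flag = "red"
    return MultipletFit(
        fractions=fractions,
        r2=r2,
        fitted_linewidth_hz=lw,
        fitted_center_hz=center,
        flag=flag,
        diagnostics={
            "picked": picked,
            "rss": float(rss),
            "tss": tss,
            "converged": bool(best.success),
            "amplitude_total": float(total),
        },
    )


def quality_flag(r2: float, green: float = 0.90, amber: float = 0.50) -> str:
    """Map a coefficient of determination to a traffic-light flag."""
    if r2 >= green:
        return "green"
    if r2 >= amber:
        return "amber"
    return "red"
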