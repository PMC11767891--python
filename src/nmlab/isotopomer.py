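"""Isotopomer distribution estimation from multiplet + mass-isotopologue data.

An *isotopomer* of an n-carbon metabolite is one of the 2^n binary
12C/13C labelling patterns; the distribution over them is a probability
vector. GC-MS observes only the popcount classes (mass isotopologues
M0..Mn); the NMR multiplet of an observable carbon sees the labelling
pattern of its coupled neighbors *conditional on the carbon itself being
labelled*. Both forward maps are linear in the isotopomer fractions once
the multiplet ratios are cross-multiplied, so the fit is a constrained
least-squares problem on the probability simplex restricted to a
user-selected isotopomer subset. Because the available observations are
usually fewer than the isotopomers of interest, the system is typically
underdetermined and the subset choice matters; the diagnostics report the
degrees of freedom and warn when they are non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import InputError, UndefinedObservationError
from .hsqc import MetaboliteEntry, neighbor_pattern_components

__all__ = [
    "IsotopomerDistribution",
    "Mid",
    "TracerObservations",
    "enumerate_isotopomers",
    "forward_mid",
    "forward_multiplet",
    "fit_isotopomers",
]

MULTISTART_SEED = 1234
N_STARTS = 5


def enumerate_isotopomers(n: int) -> list:
    """All 2^n binary labels, carbon 1 leftmost, in lexicographic order."""
    if not (1 <= n <= 12):
        raise InputError(f"carbon count must be in [1, 12], got {n}")
    return [format(i, f"0{n}b") for i in range(2 ** n)]


@dataclass
class IsotopomerDistribution:
    """Probability vector over the 2^n labelling states."""

    n_carbons: int
    x: dict

    def __post_init__(self) -> None:
        labels = enumerate_isotopomers(self.n_carbons)
        full = {lbl: 0.0 for lbl in labels}
        for k, v in self.x.items():
            if k not in full:
                raise InputError(f"label {k!r} is not a {self.n_carbons}-carbon isotopomer")
            if v < -1e-12:
                raise InputError(f"fraction of {k!r} is negative ({v})")
            full[k] = max(float(v), 0.0)
        total = sum(full.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"isotopomer fractions sum to {total}, expected 1")
        self.x = full

    def as_vector(self) -> np.ndarray:
        return np.array([self.x[lbl] for lbl in enumerate_isotopomers(self.n_carbons)])


@dataclass
class Mid:
    """Mass-isotopologue distribution M0..Mn."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < -1e-12):
            raise InputError("MID fractions must be >= 0")
        self.m = np.maximum(self.m, 0.0)
        if abs(self.m.sum() - 1.0) > 1e-9:
            raise InputError(f"MID sums to {self.m.sum()}, expected 1")


@dataclass
class TracerObservations:
    """Observed multiplet fractions per carbon plus an optional MID."""

    multiplets: dict = field(default_factory=dict)  # carbon -> {component: fraction}
    mid: Mid | None = None
    weights: dict = field(default_factory=dict)  # "mid" or carbon -> weight

    def __post_init__(self) -> None:
        for carbon, comp in self.multiplets.items():
            tot = sum(comp.values())
            if abs(tot - 1.0) > 1e-6:
                raise InputError(f"multiplet fractions of carbon {carbon} sum to {tot}")
        for k, w in self.weights.items():
            if not w > 0:
                raise InputError(f"weight for {k!r} must be > 0")
        if not self.multiplets and self.mid is None:
            raise InputError("no observations given")


def forward_mid(x: IsotopomerDistribution) -> Mid:
    """M_k = sum of isotopomer fractions whose label has k ones."""
    n = x.n_carbons
    m = np.zeros(n + 1)
    for lbl, v in x.x.items():
        m[lbl.count("1")] += v
    return Mid(m=m)


def forward_multiplet(x: IsotopomerDistribution, entry: MetaboliteEntry, carbon: int) -> dict:
    """Multiplet component fractions of ``carbon`` implied by a distribution.

    For each component (= labelled-neighbor pattern) the fraction is the
    probability of that pattern conditional on the carbon being labelled.
    Raises :class:`UndefinedObservationError` if the carbon is never
    labelled (the signal does not exist).
    """
    if not entry.observable(carbon):
        raise InputError(f"carbon {carbon} of {entry.name} is unobservable")
    if entry.n_carbons != x.n_carbons:
        raise InputError("distribution and metabolite disagree on carbon count")
    comps = neighbor_pattern_components(entry, carbon)
    nb = entry.coupled_neighbors(carbon)
    num = {label: 0.0 for label, _ in comps}
    den = 0.0
    for lbl, v in x.x.items():
        if lbl[carbon - 1] != "1":
            continue
        den += v
        labelled = tuple(j for j in nb if lbl[j - 1] == "1")
        for label, patt in comps:
            if patt == labelled:
                num[label] += v
                break
    if den <= 0:
        raise UndefinedObservationError(
            f"carbon {carbon} is never labelled under this distribution"
        )
    return {label: num[label] / den for label in num}


def _design(entry: MetaboliteEntry, obs: TracerObservations, subset: list):
    """Rows of the (linear) cross-multiplied residual system A x = b."""
    n = entry.n_carbons
    rows, rhs, wts, names = [], [], [], []
    if obs.mid is not None:
        if obs.mid.m.size != n + 1:
            raise InputError(f"MID has {obs.mid.m.size} entries, expected {n + 1}")
        w = obs.weights.get("mid", 1.0)
        for k in range(n + 1):
            row = np.array([1.0 if lbl.count("1") == k else 0.0 for lbl in subset])
            rows.append(row)
            rhs.append(obs.mid.m[k])
            wts.append(w)
            names.append(f"M{k}")
    for carbon, comp_obs in sorted(obs.multiplets.items()):
        comps = dict(neighbor_pattern_components(entry, carbon))
        nb = entry.coupled_neighbors(carbon)
        w = obs.weights.get(carbon, 1.0)
        sel = np.array([1.0 if lbl[carbon - 1] == "1" else 0.0 for lbl in subset])
        for label, frac in sorted(comp_obs.items()):
            if label not in comps:
                raise InputError(f"component {label!r} not defined for carbon {carbon}")
            patt = comps[label]
            indicator = np.array([
                1.0 if (lbl[carbon - 1] == "1"
                        and tuple(j for j in nb if lbl[j - 1] == "1") == patt)
                else 0.0
                for lbl in subset
            ])
            # cross-multiplied residual: P(pattern & labelled) - frac * P(labelled)
            rows.append(indicator - frac * sel)
            rhs.append(0.0)
            wts.append(w)
            names.append(f"C{carbon}:{label}")
    return np.vstack(rows), np.array(rhs), np.array(wts), names


def fit_isotopomers(obs: TracerObservations, entry: MetaboliteEntry, subset: list):
    """Weighted constrained least squares over a pre-selected isotopomer subset.

    Minimizes ``||W (A x - b)||^2`` subject to ``x >= 0`` and ``sum x = 1``
    with ``x = 0`` outside the subset. Multiplet ratio observations enter as
    cross-multiplied residuals, keeping the system polynomial in ``x``.
    Solved by SLSQP from several Dirichlet-random starting points (fixed
    seed) plus the uniform start; the best feasible iterate wins.

    Returns
    -------
    (IsotopomerDistribution, float, dict)
        Fitted distribution, weighted residual norm, diagnostics including
        the degrees of freedom ``n_obs - |subset| + 1`` (a warning is set
        when <= 0, the fit still proceeds).
    """
    if not subset:
        raise InputError("isotopomer subset must be non-empty")
    labels = enumerate_isotopomers(entry.n_carbons)
    for lbl in subset:
        if lbl not in labels:
            raise InputError(f"label {lbl!r} is not a {entry.n_carbons}-carbon isotopomer")
    if len(set(subset)) != len(subset):
        raise InputError("duplicate labels in subset")

    A, b, w, names = _design(entry, obs, list(subset))
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    bw = b * sw
    k = len(subset)

    def objective(x):
        r = Aw @ x - bw
        return float(r @ r)

    def grad(x):
        return 2.0 * (Aw.T @ (Aw @ x - bw))

    constraints = [{"type": "eq", "fun": lambda x: x.sum() - 1.0,
                    "jac": lambda x: np.ones_like(x)}]
    bounds = [(0.0, 1.0)] * k

    rng = np.random.default_rng(MULTISTART_SEED)
    starts = [np.full(k, 1.0 / k)]
    starts += [rng.dirichlet(np.ones(k)) for _ in range(N_STARTS)]

    best_x, best_f, converged = None, np.inf, False
    for x0 in starts:
        res = minimize(objective, x0=x0, jac=grad, method="SLSQP",
                       bounds=bounds, constraints=constraints,
                       options={"maxiter": 500, "ftol": 1e-14})
        x = np.clip(res.x, 0.0, None)
        s = x.sum()
        x = x / s if s > 0 else np.full(k, 1.0 / k)
        f = objective(x)
        if f < best_f:
            best_x, best_f = x, f
            converged = bool(res.success)

    dist = IsotopomerDistribution(
        n_carbons=entry.n_carbons,
        x={lbl: float(v) for lbl, v in zip(subset, best_x)},
    )
    # independent data points: each normalized block (MID, one carbon's
    # fraction set) carries one fewer than its row count
    n_obs = len(names)
    n_blocks = (1 if obs.mid is not None else 0) + len(obs.multiplets)
    n_independent = n_obs - n_blocks
    dof = n_independent - k + 1
    diagnostics = {
        "n_obs": n_obs,
        "n_independent": n_independent,
        "n_fitted": k,
        "dof": dof,
        "underdetermined": dof <= 0,
        "converged": converged,
        "observations": names,
        "objective": best_f,
    }
    return dist, float(np.sqrt(best_f)), diagnostics
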