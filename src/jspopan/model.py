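"""POPAN Jolly-Seber likelihood with fixed entry, fixed superpopulation, and
masked detection; model structures; maximum-likelihood fitting.

Because every release cohort enters at a known occasion and the per-group
superpopulation is fixed at the number released, the POPAN likelihood reduces
to a product-multinomial over encounter histories: each released individual,
independently, is alive at its release occasion, survives each subsequent
interval with probability phi, and (while alive) is detected at each occasion
with probability p — where p is fixed at 1 during radio-telemetry and 0 where
no survey took place.  Individuals never re-encountered contribute the
never-seen probability zeta.  The multinomial coefficient is dropped (a
data-only constant).

Model structures are named as in the field's convention, e.g.
``Phi(t+acc2019) p(t)``: ``t`` full time dependence, ``acc`` a two-level
acclimation factor (New in the first year after release, Exp after),
``acc2019`` a distinct first-interval survival for the 2019 cohort only (a
known mass-mortality year), ``2019`` a distinct 2019-2020 interval for all,
``cohort`` a release-cohort factor, ``constant`` the null.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from statsmodels.tools import numdiff

from .encounters import (
    N_OCCASIONS,
    YEARS,
    CohortGroup,
    EncounterHistory,
    MaskState,
    StudyDesign,
    ValidationError,
)

N_INTERVALS = N_OCCASIONS - 1

SURVIVAL_STRUCTURES = (
    "constant", "t", "acc", "cohort", "t*acc", "t+acc",
    "t+acc2019", "acc+t2019", "acc2019", "2019",
)
DETECTION_STRUCTURES = ("constant", "t", "t+acc", "t*acc")

#: Interval index of the 2019 sampling year (2019 -> 2020).
_T2019 = YEARS.index(2019)


@dataclass(frozen=True)
class ModelSpec:
    """A named survival x detection submodel structure."""

    survival: str
    detection: str

    def __post_init__(self) -> None:
        if self.survival not in SURVIVAL_STRUCTURES:
            raise ValueError(f"unknown survival structure {self.survival!r}")
        if self.detection not in DETECTION_STRUCTURES:
            raise ValueError(f"unknown detection structure {self.detection!r}")

    @property
    def name(self) -> str:
        return f"Phi({self.survival}) p({self.detection})"

    @classmethod
    def parse(cls, name: str) -> "ModelSpec":
        m = re.fullmatch(
            r"\s*Phi\(([^)]+)\)\s*p\(([^)]+)\)\s*", name, flags=re.IGNORECASE
        )
        if not m:
            raise ValueError(f"cannot parse model name {name!r}")
        return cls(m.group(1).strip(), m.group(2).strip())


#: The published candidate set (18 models).
CANDIDATE_MODELS: tuple[str, ...] = (
    "Phi(t+acc2019) p(t)",
    "Phi(t+acc2019) p(t*acc)",
    "Phi(t+acc2019) p(t+acc)",
    "Phi(acc2019) p(t)",
    "Phi(acc+t2019) p(t)",
    "Phi(acc+t2019) p(t*acc)",
    "Phi(acc+t2019) p(t+acc)",
    "Phi(t*acc) p(t)",
    "Phi(acc2019) p(t*acc)",
    "Phi(acc2019) p(t+acc)",
    "Phi(cohort) p(t)",
    "Phi(t*acc) p(t*acc)",
    "Phi(cohort) p(t*acc)",
    "Phi(cohort) p(t+acc)",
    "Phi(t) p(t)",
    "Phi(t) p(t*acc)",
    "Phi(t) p(t+acc)",
    "Phi(2019) p(t*acc)",
)


# ---------------------------------------------------------------------------
# Parameter index matrices
# ---------------------------------------------------------------------------

@dataclass
class ParameterIndexMatrix:
    """Maps design cells to estimable link-scale parameters.

    Survival cells are (group, interval) pairs for intervals from the group's
    release occasion; detection cells are the FREE (group, occasion) cells.
    Each cell's logit-scale value is ``X @ beta`` over its block's design
    matrix.  One-hot structures give each cell exactly one parameter id;
    additive structures combine a time id with an effect id.  Ids are
    contiguous, survival block first.
    """

    phi_cells: list[tuple[int, int]]       # (group index, interval)
    p_cells: list[tuple[int, int]]         # (group index, occasion)
    X_phi: np.ndarray                      # (n phi cells, k_phi)
    X_p: np.ndarray                        # (n p cells, k_p)
    phi_labels: list[str]
    p_labels: list[str]

    @property
    def k_phi(self) -> int:
        return self.X_phi.shape[1]

    @property
    def k_p(self) -> int:
        return self.X_p.shape[1]

    @property
    def n_params(self) -> int:
        return self.k_phi + self.k_p

    @property
    def labels(self) -> list[str]:
        return [f"phi:{l}" for l in self.phi_labels] + [f"p:{l}" for l in self.p_labels]

    def to_frame(self, design: StudyDesign) -> pd.DataFrame:
        """Cell-by-cell export: contributing parameter ids (1-based) or fix."""
        rows = []
        for (c, X, labels, kind, offset) in (
            (self.phi_cells, self.X_phi, self.phi_labels, "phi", 0),
            (self.p_cells, self.X_p, self.p_labels, "p", self.k_phi),
        ):
            for cell, xrow in zip(c, X):
                g, t = cell
                grp = design.groups[g]
                ids = [offset + j + 1 for j in np.flatnonzero(xrow)]
                rows.append(
                    {
                        "kind": kind,
                        "group": f"{grp.cohort}_d{grp.telemetry_occasions}",
                        "index": t,
                        "parameter_ids": "+".join(str(i) for i in ids),
                        "fixed": "",
                    }
                )
        for g, grp in enumerate(design.groups):
            for t in range(design.n_occasions):
                st = design.detection_mask[g, t]
                if st is not MaskState.FREE:
                    rows.append(
                        {
                            "kind": "p",
                            "group": f"{grp.cohort}_d{grp.telemetry_occasions}",
                            "index": t,
                            "parameter_ids": "",
                            "fixed": "1" if st is MaskState.FIXED_1 else "0",
                        }
                    )
        return pd.DataFrame(rows)


def _onehot(levels: Sequence, values: Sequence) -> tuple[np.ndarray, list]:
    """One-hot design matrix over the realized levels (unrealized dropped)."""
    realized = [lv for lv in levels if lv in set(values)]
    X = np.zeros((len(values), len(realized)))
    for i, v in enumerate(values):
        X[i, realized.index(v)] = 1.0
    return X, realized


def build_parameter_index(design: StudyDesign, spec: ModelSpec) -> ParameterIndexMatrix:
    """Construct the design matrices realizing ``spec`` on ``design``.

    ``k = n_params`` is the structural count: only factor combinations realized
    by at least one cell contribute a parameter.
    """
    # --- survival cells: every interval from release onward, per group
    phi_cells: list[tuple[int, int]] = []
    for g, grp in enumerate(design.groups):
        for t in range(grp.release_occasion, N_INTERVALS):
            phi_cells.append((g, t))

    def phi_features(cell):
        g, t = cell
        grp = design.groups[g]
        new = t == grp.release_occasion
        return {
            "t": t,
            "acc": "New" if new else "Exp",
            "cohort": grp.cohort,
            "acc2019": new and grp.cohort == 2019,
            "t2019": t == _T2019,
        }

    feats = [phi_features(c) for c in phi_cells]
    s = spec.survival
    if not phi_cells:
        X_phi = np.zeros((0, 0))
        phi_labels = []
    elif s == "constant":
        X_phi = np.ones((len(phi_cells), 1))
        phi_labels = ["const"]
    elif s == "t":
        X_phi, lv = _onehot(range(N_INTERVALS), [f["t"] for f in feats])
        phi_labels = [f"{YEARS[t]}-{YEARS[t + 1]}" for t in lv]
    elif s == "acc":
        X_phi, lv = _onehot(["New", "Exp"], [f["acc"] for f in feats])
        phi_labels = list(lv)
    elif s == "cohort":
        X_phi, lv = _onehot(sorted({f["cohort"] for f in feats}), [f["cohort"] for f in feats])
        phi_labels = [str(c) for c in lv]
    elif s == "t*acc":
        combos = [(f["t"], f["acc"]) for f in feats]
        levels = sorted(set(combos))
        X_phi, lv = _onehot(levels, combos)
        phi_labels = [f"{YEARS[t]}-{YEARS[t + 1]}:{a}" for t, a in lv]
    elif s == "t+acc":
        Xt, lvt = _onehot(range(N_INTERVALS), [f["t"] for f in feats])
        Xa = np.array([[1.0] if f["acc"] == "New" else [0.0] for f in feats])
        X_phi = np.hstack([Xt, Xa])
        phi_labels = [f"{YEARS[t]}-{YEARS[t + 1]}" for t in lvt] + ["New"]
    elif s == "t+acc2019":
        Xt, lvt = _onehot(range(N_INTERVALS), [f["t"] for f in feats])
        Xa = np.array([[1.0] if f["acc2019"] else [0.0] for f in feats])
        X_phi = np.hstack([Xt, Xa])
        phi_labels = [f"{YEARS[t]}-{YEARS[t + 1]}" for t in lvt] + ["acc2019"]
    elif s == "acc+t2019":
        Xa, lva = _onehot(["New", "Exp"], [f["acc"] for f in feats])
        Xt = np.array([[1.0] if f["t2019"] else [0.0] for f in feats])
        X_phi = np.hstack([Xa, Xt])
        phi_labels = list(lva) + ["t2019"]
    elif s == "acc2019":
        X_phi, lv = _onehot([False, True], [f["acc2019"] for f in feats])
        phi_labels = ["baseline" if not v else "2019 New" for v in lv]
    elif s == "2019":
        X_phi, lv = _onehot([False, True], [f["t2019"] for f in feats])
        phi_labels = ["baseline" if not v else "2019-2020" for v in lv]
    else:  # pragma: no cover
        raise AssertionError(s)

    # --- detection cells: FREE cells only
    p_cells = [
        (g, t)
        for g in range(design.n_groups)
        for t in range(design.n_occasions)
        if design.detection_mask[g, t] is MaskState.FREE
    ]

    def p_features(cell):
        g, t = cell
        grp = design.groups[g]
        return {"t": t, "acc": "New" if t == grp.release_occasion else "Exp"}

    pf = [p_features(c) for c in p_cells]
    d = spec.detection
    if not p_cells:
        X_p = np.zeros((0, 0))
        p_labels = []
    elif d == "constant":
        X_p = np.ones((len(p_cells), 1))
        p_labels = ["const"]
    elif d == "t":
        X_p, lv = _onehot(range(N_OCCASIONS), [f["t"] for f in pf])
        p_labels = [str(YEARS[t]) for t in lv]
    elif d == "t*acc":
        combos = [(f["t"], f["acc"]) for f in pf]
        X_p, lv = _onehot(sorted(set(combos)), combos)
        p_labels = [f"{YEARS[t]}:{a}" for t, a in lv]
    elif d == "t+acc":
        Xt, lvt = _onehot(range(N_OCCASIONS), [f["t"] for f in pf])
        Xa = np.array([[1.0] if f["acc"] == "New" else [0.0] for f in pf])
        X_p = np.hstack([Xt, Xa])
        p_labels = [str(YEARS[t]) for t in lvt] + ["New"]
    else:  # pragma: no cover
        raise AssertionError(d)

    return ParameterIndexMatrix(
        phi_cells=phi_cells,
        p_cells=p_cells,
        X_phi=np.asarray(X_phi, dtype=float),
        X_p=np.asarray(X_p, dtype=float),
        phi_labels=phi_labels,
        p_labels=p_labels,
    )


# ---------------------------------------------------------------------------
# Recursions and history probabilities
# ---------------------------------------------------------------------------

def nonencounter_recursion(
    phi: Sequence[float], p: Sequence[float], start: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Never-seen and never-seen-again recursions for one group.

    ``phi[t]`` is survival over interval (t, t+1); ``p[t]`` detection at
    occasion t (fixed values already substituted).  Returns
    ``(zeta_start, zeta, chi)`` where ``zeta[t]`` is the probability an animal
    alive at t is never detected at t or later, and ``chi[t]`` the probability
    it is never detected *after* t, given alive at t:

        zeta[T-1] = 1 - p[T-1]
        zeta[t]   = (1 - p[t]) * ((1 - phi[t]) + phi[t] * zeta[t+1])
        chi[T-1]  = 1
        chi[t]    = (1 - phi[t]) + phi[t] * (1 - p[t+1]) * chi[t+1]
    """
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    T = len(p)
    if np.any((p < 0) | (p > 1)) or np.any((phi[start:] < 0) | (phi[start:] > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    zeta = np.ones(T)
    chi = np.ones(T)
    zeta[T - 1] = 1.0 - p[T - 1]
    for t in range(T - 2, start - 1, -1):
        zeta[t] = (1.0 - p[t]) * ((1.0 - phi[t]) + phi[t] * zeta[t + 1])
        chi[t] = (1.0 - phi[t]) + phi[t] * (1.0 - p[t + 1]) * chi[t + 1]
    return float(zeta[start]), zeta, chi


def history_probability(
    detections: Sequence[int], release: int, phi: Sequence[float], p: Sequence[float]
) -> float:
    """Probability of one encounter history given entry at ``release``.

    For first detection f and last detection l,
    ``P = prod_{t=r..f-1}(1-p_t)phi_t * p_f *
    prod_{t=f..l-1} phi_t p_{t+1}^{x} (1-p_{t+1})^{1-x} * chi_l``;
    the all-zero history has ``P = zeta_r``.
    """
    x = np.asarray(detections, dtype=int)
    if x[:release].any():
        raise ValidationError("detection before release occasion")
    zeta_r, _, chi = nonencounter_recursion(phi, p, release)
    if not x.any():
        return zeta_r
    idx = np.flatnonzero(x)
    f, l = int(idx[0]), int(idx[-1])
    prob = 1.0
    for t in range(release, l):
        prob *= phi[t]
    for t in range(release, l + 1):
        prob *= p[t] if x[t] else (1.0 - p[t])
    return prob * chi[l]


def _group_history_logprobs(
    H: np.ndarray, release: int, phi: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, float]:
    """Vectorized log-probabilities for a stack of histories of one group.

    Returns (logP per history row, log zeta at release).  Rows that are
    impossible under the fixed detection values get -inf.
    """
    T = len(p)
    with np.errstate(divide="ignore"):
        A = np.log1p(-p)          # log(1 - p_t)
        B = np.log(p)             # log p_t
        C = np.zeros(N_INTERVALS)
        C[release:] = np.log(phi[release:])
    zeta_r, _, chi = nonencounter_recursion(phi, p, release)
    with np.errstate(divide="ignore"):
        log_chi = np.log(chi)
        log_zeta_r = np.log(zeta_r) if zeta_r > 0 else -np.inf

    Hb = H.astype(bool)
    det = np.where(Hb, B[None, :], A[None, :])           # (m, T)
    cum_det = np.cumsum(det, axis=1)
    cum_C = np.concatenate([[0.0], np.cumsum(C)])        # cum_C[l] = sum_{t<l} C

    any_det = Hb.any(axis=1)
    logP = np.full(H.shape[0], log_zeta_r)
    if any_det.any():
        last = np.where(any_det, T - 1 - np.argmax(Hb[:, ::-1], axis=1), 0)
        sel = np.flatnonzero(any_det)
        l = last[sel]
        logP[sel] = cum_det[sel, l] + cum_C[l] + log_chi[l]
    return logP, log_zeta_r


@dataclass
class LikelihoodValue:
    loglik: float
    per_group_loglik: dict[tuple[int, int], float]
    dropped_constant: bool = True


@dataclass
class GroupData:
    """Aggregated encounter data of one design group."""

    group: CohortGroup
    histories: np.ndarray      # (m, T) unique observed histories (may incl. all-zero)
    counts: np.ndarray         # (m,)
    n_unobserved: int          # released but absent from the table

    @property
    def m_observed(self) -> int:
        obs = self.histories.any(axis=1)
        return int(self.counts[obs].sum())


def prepare_data(
    histories: Iterable[EncounterHistory], design: StudyDesign
) -> list[GroupData]:
    """Group and aggregate histories against a design; validates consistency."""
    gi = design.group_index()
    per_group: dict[tuple[int, int], dict[tuple[int, ...], int]] = {
        k: {} for k in gi
    }
    for h in histories:
        key = (h.cohort, h.telemetry_occasions)
        if key not in gi:
            raise ValidationError(
                f"{h.individual_id}: no design group for cohort {h.cohort}, "
                f"telemetry {h.telemetry_occasions}"
            )
        g = gi[key]
        for t, x in enumerate(h.detections):
            if x and design.detection_mask[g, t] is MaskState.FIXED_0:
                raise ValidationError(
                    f"{h.individual_id}: detection at fixed-zero occasion "
                    f"{design.years[t]}"
                )
        per_group[key][h.detections] = per_group[key].get(h.detections, 0) + 1
    out = []
    for key, g in gi.items():
        grp = design.groups[g]
        items = sorted(per_group[key].items())
        H = (
            np.array([list(h) for h, _ in items], dtype=np.int8)
            if items
            else np.zeros((0, design.n_occasions), dtype=np.int8)
        )
        counts = np.array([c for _, c in items], dtype=float)
        n_rows = int(counts.sum())
        if n_rows > grp.n_released:
            raise ValidationError(
                f"group {key}: {n_rows} individuals exceed the {grp.n_released} released"
            )
        out.append(
            GroupData(
                group=grp,
                histories=H,
                counts=counts,
                n_unobserved=grp.n_released - n_rows,
            )
        )
    return out


def resolve_cell_probs(
    design: StudyDesign, pim: ParameterIndexMatrix, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-link transform theta and scatter into (Phi, P) cell matrices.

    Fixed detection cells carry their 0/1 values; survival before release is
    left as NaN (never used).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (pim.n_params,):
        raise ValueError(f"theta must have length {pim.n_params}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter vector")
    beta_phi = theta[: pim.k_phi]
    beta_p = theta[pim.k_phi:]
    Phi = np.full((design.n_groups, N_INTERVALS), np.nan)
    P = np.zeros((design.n_groups, design.n_occasions))
    for g in range(design.n_groups):
        for t in range(design.n_occasions):
            if design.detection_mask[g, t] is MaskState.FIXED_1:
                P[g, t] = 1.0
    if pim.phi_cells:
        vals = expit(pim.X_phi @ beta_phi)
        for (g, t), v in zip(pim.phi_cells, vals):
            Phi[g, t] = v
    if pim.p_cells:
        vals = expit(pim.X_p @ beta_p)
        for (g, t), v in zip(pim.p_cells, vals):
            P[g, t] = v
    return Phi, P


def group_loglik(gd: GroupData, phi: np.ndarray, p: np.ndarray) -> float:
    """Log-likelihood contribution of one group (multinomial constant dropped).

    ``ln L_g = sum_observed ln P(history) + n_unobserved * ln zeta_release``.
    """
    r = gd.group.release_occasion
    if gd.histories.shape[0]:
        logP, log_zeta = _group_history_logprobs(gd.histories, r, phi, p)
        ll = float(np.dot(gd.counts, logP))
    else:
        _, log_zeta = _group_history_logprobs(
            np.zeros((1, len(p)), dtype=np.int8), r, phi, p
        )
        ll = 0.0
    if gd.n_unobserved:
        ll += gd.n_unobserved * log_zeta
    return ll


def total_loglik(
    data: Sequence[GroupData],
    design: StudyDesign,
    pim: ParameterIndexMatrix,
    theta: np.ndarray,
) -> LikelihoodValue:
    """Sum of group log-likelihoods at link-scale parameter vector theta."""
    Phi, P = resolve_cell_probs(design, pim, theta)
    gi = design.group_index()
    per_group = {}
    total = 0.0
    for gd in data:
        g = gi[gd.group.key]
        ll = group_loglik(gd, Phi[g], P[g])
        per_group[gd.group.key] = ll
        total += ll
    return LikelihoodValue(loglik=total, per_group_loglik=per_group)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """MLE on the link scale with asymptotic covariance and bookkeeping."""

    spec: ModelSpec
    pim: ParameterIndexMatrix
    design: StudyDesign
    beta: np.ndarray               # link-scale MLE, length k
    covariance: np.ndarray         # link-scale covariance, (k, k)
    loglik_max: float
    converged: bool
    boundary_flags: np.ndarray     # bool per parameter
    n_restarts_used: int = 0
    data_fingerprint: tuple = ()

    @property
    def k(self) -> int:
        return self.pim.n_params

    @property
    def param_labels(self) -> list[str]:
        return self.pim.labels

    @property
    def estimates(self) -> np.ndarray:
        """Back-transformed estimates.  For one-hot structures each entry is
        the cell probability; additive effect entries are contrasts and are
        interpretable only through :meth:`cell_probs`."""
        return expit(self.beta)

    def se(self) -> np.ndarray:
        d = np.diag(self.covariance)
        return np.sqrt(np.where(d > 0, d, np.nan))

    def cell_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """Fitted (Phi, P) matrices over design cells."""
        return resolve_cell_probs(self.design, self.pim, self.beta)

    @property
    def deviance(self) -> float:
        """-2 log L under the dropped-multinomial-constant convention."""
        return -2.0 * self.loglik_max


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, best: FitResult | None = None):
        super().__init__(msg)
        self.best = best


def _fingerprint(data: Sequence[GroupData]) -> tuple:
    return tuple(
        (gd.group.key, gd.group.n_released, gd.histories.tobytes(), gd.counts.tobytes())
        for gd in data
    )


def fit_mle(
    data: Sequence[GroupData],
    design: StudyDesign,
    spec: ModelSpec,
    *,
    start: np.ndarray | None = None,
    n_restarts: int = 5,
    tol: float = 1e-8,
    maxiter: int = 500,
    seed: int = 0,
) -> FitResult:
    """Maximize the likelihood over link-scale parameters.

    Quasi-Newton (L-BFGS-B) with finite-difference gradients; on failure,
    up to ``n_restarts`` seeded random restarts jittered around the start.
    The covariance is the inverse negative Hessian (finite differences) at
    the optimum; boundary or Hessian-singular parameters are flagged.
    """
    pim = build_parameter_index(design, spec)
    k = pim.n_params
    if k == 0:
        raise ValidationError("model has no free parameters")

    def negll(theta):
        with np.errstate(invalid="ignore"):
            v = total_loglik(data, design, pim, theta).loglik
        return np.inf if not np.isfinite(v) else -v

    rng = np.random.default_rng(seed)
    x0 = np.zeros(k) if start is None else np.asarray(start, dtype=float)
    best = None
    tried = 0
    for attempt in range(n_restarts + 1):
        xs = x0 if attempt == 0 else x0 + rng.normal(scale=1.5, size=k)
        res = optimize.minimize(
            negll,
            xs,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        tried = attempt
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            break
    assert best is not None
    beta = np.asarray(best.x, dtype=float)

    H = numdiff.approx_hess2(beta, negll)
    boundary = np.abs(beta) > 9.0
    cov = np.full((k, k), np.nan)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    diag = np.diag(cov)
    bad = ~np.isfinite(diag) | (diag <= 0)
    flags = boundary | bad
    fit = FitResult(
        spec=spec,
        pim=pim,
        design=design,
        beta=beta,
        covariance=cov,
        loglik_max=-float(best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
        boundary_flags=flags,
        n_restarts_used=tried,
        data_fingerprint=_fingerprint(data),
    )
    if not fit.converged:
        raise ConvergenceError(
            f"{spec.name}: optimizer failed after {n_restarts} restarts", best=fit
        )
    return fit


def wald_ci(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter Wald intervals on the logit scale, back-transformed.

    Boundary-flagged or inestimable parameters are marked unreliable.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se()
    lo = expit(fit.beta - z * np.where(np.isnan(se), 0.0, se))
    hi = expit(fit.beta + z * np.where(np.isnan(se), 0.0, se))
    return pd.DataFrame(
        {
            "parameter": fit.param_labels,
            "estimate": fit.estimates,
            "beta": fit.beta,
            "se_link": se,
            "lo": lo,
            "hi": hi,
            "unreliable": fit.boundary_flags | np.isnan(se),
        }
    )
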