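"""Model ranking (AICc, Akaike weights), Fletcher c-hat goodness of fit, and
derived abundance with Delta-method confidence intervals.

Abundance is a derived quantity here: with entry fixed at the release occasion
and the group superpopulation fixed at the number released, the expected
number alive follows the recursion ``N[g, r] = n_released`` and
``N[g, t+1] = N[g, t] * phi[g, t]``; occasion totals sum over groups.  The
variance of a total is obtained by first-order (Delta-method) propagation of
the link-scale covariance through that recursion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .encounters import N_OCCASIONS, StudyDesign, ValidationError
from .model import (
    FitResult,
    GroupData,
    ModelSpec,
    _group_history_logprobs,
    build_parameter_index,
    resolve_cell_probs,
    total_loglik,
)

#: Default effective sample size for AICc: the analysis superpopulation.
DEFAULT_N_EFF = 260


def aicc(loglik: float, k: int, n_eff: int) -> float:
    """Small-sample Akaike criterion: -2logL + 2k + 2k(k+1)/(n_eff - k - 1)."""
    if n_eff <= k + 1:
        raise ValueError(f"n_eff={n_eff} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_eff - k - 1)


def rank_models(
    fits: Sequence[FitResult], n_eff: int = DEFAULT_N_EFF
) -> pd.DataFrame:
    """Rank fitted models by AICc with Akaike weights.

    All fits must be of the same data.  The ``preferred`` column annotates the
    parsimony recommendation: among models within 2 AICc of the best, the one
    with fewest parameters (reported, not auto-selected).
    """
    if not fits:
        raise ValueError("no fits to rank")
    fp = fits[0].data_fingerprint
    for f in fits[1:]:
        if f.data_fingerprint != fp:
            raise ValidationError("fits were not made on identical data")
    rows = [
        {
            "model": f.spec.name,
            "k": f.k,
            "aicc": aicc(f.loglik_max, f.k, n_eff),
            "deviance": f.deviance,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    w = np.exp(-df["delta_aicc"] / 2.0)
    df["weight"] = w / w.sum()
    close = df["delta_aicc"] < 2.0
    pick = df.loc[close, "k"].idxmin() if close.any() else df.index[0]
    df["preferred"] = False
    df.loc[pick, "preferred"] = True
    return df[["model", "k", "aicc", "delta_aicc", "weight", "deviance", "preferred"]]


# ---------------------------------------------------------------------------
# Fletcher c-hat
# ---------------------------------------------------------------------------

def _group_cells(gd: GroupData, phi: np.ndarray, p: np.ndarray):
    """Observed and expected counts over the group's possible histories.

    Enumerates all binary histories over the post-release occasions, keeps
    those with positive probability under the fitted parameters (histories
    contradicting a p=1 telemetry fix have probability zero and are not
    multinomial cells), and matches them with observed counts.  The never-seen
    (all-zero) cell absorbs the released-but-unobserved individuals.
    """
    r = gd.group.release_occasion
    T = N_OCCASIONS
    span = T - r
    combos = np.array(list(itertools.product((0, 1), repeat=span)), dtype=np.int8)
    H = np.zeros((combos.shape[0], T), dtype=np.int8)
    H[:, r:] = combos
    logP, _ = _group_history_logprobs(H, r, phi, p)
    keep = np.isfinite(logP)
    H, logP = H[keep], logP[keep]
    expected = gd.group.n_released * np.exp(logP)
    observed = np.zeros(len(H))
    lookup = {tuple(row): i for i, row in enumerate(H)}
    for row, c in zip(gd.histories, gd.counts):
        key = tuple(int(v) for v in row)
        if key in lookup:
            observed[lookup[key]] += c
    zero_key = tuple([0] * T)
    if gd.n_unobserved and zero_key in lookup:
        observed[lookup[zero_key]] += gd.n_unobserved
    return observed, expected


def fletcher_chat(data: Sequence[GroupData], fit: FitResult) -> float:
    """Fletcher's overdispersion estimate for a fitted model.

    ``chat = (X2 / df) / (1 + sbar)`` with ``X2`` the Pearson statistic over
    all positive-probability history cells (including the never-seen cell),
    ``df = cells - k - groups`` and ``sbar`` the mean of
    ``(observed - expected) / expected``.  Values near 1 indicate adequate
    fit; values well above 1 indicate overdispersion.
    """
    Phi, P = fit.cell_probs()
    X2 = 0.0
    sbar_terms = []
    n_cells = 0
    for g, gd in enumerate(data):
        obs, exp = _group_cells(gd, Phi[g], P[g])
        X2 += float(np.sum((obs - exp) ** 2 / exp))
        sbar_terms.append((obs - exp) / exp)
        n_cells += len(exp)
    df = n_cells - fit.k - len(data)
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    sbar = float(np.mean(np.concatenate(sbar_terms)))
    return (X2 / df) / (1.0 + sbar)


# ---------------------------------------------------------------------------
# Derived abundance
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTrajectory:
    """Per-group and total expected abundance by occasion, with 95% CIs."""

    years: tuple[int, ...]
    per_group: np.ndarray    # (G, T); 0 before release
    totals: np.ndarray       # (T,)
    se: np.ndarray | None = None
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def to_frame(self, design: StudyDesign) -> pd.DataFrame:
        rows = []
        for t, y in enumerate(self.years):
            row = {"year": y, "total": self.totals[t]}
            if self.se is not None:
                row.update(se=self.se[t], lo=self.lo[t], hi=self.hi[t])
            for g, grp in enumerate(design.groups):
                row[f"{grp.cohort}_d{grp.telemetry_occasions}"] = self.per_group[g, t]
            rows.append(row)
        return pd.DataFrame(rows)


def _trajectory_from_phi(design: StudyDesign, Phi: np.ndarray) -> np.ndarray:
    G, T = design.n_groups, design.n_occasions
    N = np.zeros((G, T))
    for g, grp in enumerate(design.groups):
        r = grp.release_occasion
        N[g, r] = grp.n_released
        for t in range(r, T - 1):
            if not np.isfinite(Phi[g, t]):
                raise ValidationError(
                    f"missing survival for group {grp.key}, interval {t}"
                )
            N[g, t + 1] = N[g, t] * Phi[g, t]
    return N


def abundance_from_survival(
    design: StudyDesign, phi_by_cell: np.ndarray
) -> AbundanceTrajectory:
    """Abundance recursion from an explicit (G, intervals) survival matrix.

    Useful for closed-form hand checks, e.g. plugging in printed estimates.
    """
    N = _trajectory_from_phi(design, np.asarray(phi_by_cell, dtype=float))
    return AbundanceTrajectory(
        years=design.years, per_group=N, totals=N.sum(axis=0)
    )


def derive_abundance(fit: FitResult, design: StudyDesign) -> AbundanceTrajectory:
    """Expected abundance per occasion implied by the fitted survival."""
    Phi, _ = fit.cell_probs()
    return abundance_from_survival(design, Phi)


def delta_method_ci(
    fit: FitResult,
    design: StudyDesign,
    trajectory: AbundanceTrajectory | None = None,
    level: float = 0.95,
) -> AbundanceTrajectory:
    """Delta-method confidence intervals for the occasion totals.

    The gradient of each total with respect to the link-scale parameters is
    taken by central finite differences and sandwiched with the fitted
    covariance; intervals are normal-approximation, floored at 0.
    """
    if trajectory is None:
        trajectory = derive_abundance(fit, design)

    def totals_at(theta: np.ndarray) -> np.ndarray:
        Phi, _ = resolve_cell_probs(design, fit.pim, theta)
        return _trajectory_from_phi(design, Phi).sum(axis=0)

    k = fit.k
    h = 1e-5
    J = np.zeros((design.n_occasions, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        J[:, j] = (totals_at(fit.beta + e) - totals_at(fit.beta - e)) / (2 * h)
    cov = np.where(np.isfinite(fit.covariance), fit.covariance, 0.0)
    var = np.einsum("tj,jk,tk->t", J, cov, J)
    var = np.where(var > 0, var, 0.0)
    se = np.sqrt(var)
    z = norm.ppf(0.5 + level / 2.0)
    lo = np.maximum(trajectory.totals - z * se, 0.0)
    hi = trajectory.totals + z * se
    return AbundanceTrajectory(
        years=trajectory.years,
        per_group=trajectory.per_group,
        totals=trajectory.totals,
        se=se,
        lo=lo,
        hi=hi,
    )


def density(total_abundance: float, area_ha: float) -> tuple[int, float]:
    """Turtles per hectare: (nearest integer, unrounded)."""
    if area_ha <= 0:
        raise ValueError("area must be positive")
    d = total_abundance / area_ha
    return int(round(d)), d
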