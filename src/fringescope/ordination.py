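"""Ordination statistics: NMDS, vector fitting, RDA and CCA tests.

NMDS follows Kruskal's scheme: alternate a pool-adjacent-violators monotone
regression of configuration distances on the rank order of the observed
dissimilarities with a Guttman-transform configuration update, accepting
steps only when stress-1 does not increase (step-halving otherwise), over
one classical-scaling start plus random restarts.  Environmental vectors
are fitted post hoc by least squares on the ordination axes with
permutation p-values.  RDA attributes percent community variance to single
constraints or their span; CCA tests fringe-group separation on
chi-square-standardized abundances with a per-axis permutation ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .community import DistanceMatrix
from .data_model import ASVTable, GeochemTable


class OrdinationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# monotone regression

def monotone_regression(
    y: Sequence[float],
    keys: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Least-squares monotone non-decreasing fit of ``y``.

    ``keys`` defines the ordering (defaults to the positions of ``y``);
    entries with equal keys are pooled to a common fitted value before the
    pool-adjacent-violators pass, so ties never constrain each other's
    order.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if keys is None:
        res = isotonic_regression(y, weights=w, increasing=True)
        return np.asarray(res.x)

    keys = np.asarray(keys)
    order = np.argsort(keys, kind="stable")
    ys, ws, ks = y[order], w[order], keys[order]
    # pool tied keys into blocks
    block_start = np.flatnonzero(np.r_[True, ks[1:] != ks[:-1]])
    block_id = np.cumsum(np.r_[True, ks[1:] != ks[:-1]]) - 1
    bw = np.bincount(block_id, weights=ws)
    by = np.bincount(block_id, weights=ws * ys) / bw
    fit_blocks = np.asarray(isotonic_regression(by, weights=bw, increasing=True).x)
    fitted_sorted = fit_blocks[block_id]
    out = np.empty_like(y)
    out[order] = fitted_sorted
    return out


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray            # n × k, centered, principal-axis rotated
    stress: float                      # Kruskal stress-1
    n_restarts: int
    converged: bool
    seed: int | None
    stress_history: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=[f"NMDS{i + 1}" for i in range(k)])


def _stress1(dhat: np.ndarray, dconf: np.ndarray) -> float:
    denom = float((dhat ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dconf) ** 2).sum() / denom))


def _guttman(X: np.ndarray, dhat_sq: np.ndarray, dconf: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dconf > 0, dhat_sq / dconf, 0.0)
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _nmds_single(
    dobs: np.ndarray, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    X = X0.copy()
    dconf = pdist(X)
    dhat = monotone_regression(dconf, keys=dobs)
    stress = _stress1(dhat, dconf)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        Xg = _guttman(X, dhat, dconf)
        alpha = 1.0
        while True:
            Xc = X + alpha * (Xg - X)
            dc = pdist(Xc)
            dh = monotone_regression(dc, keys=dobs)
            sc = _stress1(dh, dc)
            if sc <= stress or alpha < 1e-4:
                break
            alpha /= 2.0
        if sc > stress:          # no non-increasing step found
            converged = True
            break
        improved = stress - sc
        X, dconf, dhat, stress = Xc, dc, dh, sc
        history.append(stress)
        if improved < tol:
            converged = True
            break
    return X, stress, converged, history


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    One classical-scaling warm start plus ``n_restarts − 1`` random starts;
    the best final configuration is returned centered and rotated to its
    principal axes.  Stress is non-increasing within every run by
    construction.
    """
    n = len(d.sample_ids)
    if n <= k:
        raise OrdinationError(f"need more than {k} samples for k={k}")
    dobs = d.condensed()
    rng = np.random.default_rng(seed)

    best = None
    for r in range(max(1, n_restarts)):
        X0 = _classical_scaling(d.values, k) if r == 0 else rng.normal(size=(n, k))
        X, stress, conv, history = _nmds_single(dobs, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, conv, history)

    X, stress, conv, history = best
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    return OrdinationResult(list(d.sample_ids), X, stress, max(1, n_restarts),
                            conv, seed, history)


# ---------------------------------------------------------------------------
# envfit

@dataclass
class FittedVector:
    variable: str
    direction: np.ndarray        # unit k-vector
    r_squared: float
    p_value: float
    n_perm: int
    defined: bool = True


def envfit(
    ordination: OrdinationResult,
    g: GeochemTable,
    variables: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
) -> list[FittedVector]:
    """Least-squares fit of each geochemical variable on the ordination axes.

    r² = 1 − SS_res/SS_tot for the regression of the centered variable on
    the sample coordinates; the permutation p-value is the +1-corrected
    exceedance probability of r² under random relabelling of the variable's
    values across samples.  Constant variables are returned flagged with
    undefined r².
    """
    variables = list(variables) if variables is not None else g.variables
    coords = ordination.coordinates
    vals = g.values.loc[ordination.sample_ids, variables]
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(coords - coords.mean(axis=0))

    out = []
    for var in variables:
        v = vals[var].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise OrdinationError(f"missing values in {var!r}; envfit needs complete data")
        vc = v - v.mean()
        ss_tot = float(vc @ vc)
        if ss_tot == 0:
            out.append(FittedVector(var, np.zeros(coords.shape[1]), np.nan,
                                    np.nan, n_perm, defined=False))
            continue
        beta, *_ = np.linalg.lstsq(coords - coords.mean(axis=0), vc, rcond=None)
        r2 = float((Q.T @ vc) @ (Q.T @ vc) / ss_tot)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        exceed = 0
        for _ in range(n_perm):
            vp = rng.permutation(vc)
            r2p = float((Q.T @ vp) @ (Q.T @ vp) / ss_tot)
            if r2p >= r2:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        out.append(FittedVector(var, direction, r2, p, n_perm))
    return out


# ---------------------------------------------------------------------------
# RDA

@dataclass
class VarianceContribution:
    variable: str                # a variable name or "combined"
    percent: float


def _constraint_matrix(g: GeochemTable, sample_ids, variables) -> np.ndarray:
    X = g.values.loc[sample_ids, list(variables)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise OrdinationError("missing values in constraints")
    return X - X.mean(axis=0)


def rda_contribution(
    t: ASVTable,
    g: GeochemTable,
    variables: Sequence[str],
    include_combined: bool = True,
) -> list[VarianceContribution]:
    """Percent of total community variance explained by each constraint.

    For a single centered variable x the contribution is
    100·tr(ŶᵀŶ)/tr(YᵀY) with Ŷ the projection of the column-centered
    community matrix Y onto x — the marginal fraction, so single percents
    need not sum to the combined span's percent unless the constraints are
    orthogonal.
    """
    Y = t.counts.to_numpy(dtype=float).T          # samples × taxa
    sample_ids = t.sample_ids
    Y = Y - Y.mean(axis=0)
    total = float((Y ** 2).sum())
    if total == 0:
        raise OrdinationError("community matrix has no variance")

    out = []
    for var in variables:
        x = _constraint_matrix(g, sample_ids, [var])
        ssx = float((x ** 2).sum())
        if ssx == 0:
            raise OrdinationError(f"constraint {var!r} is constant")
        proj = x @ (x.T @ Y) / ssx
        out.append(VarianceContribution(var, 100.0 * float((proj ** 2).sum()) / total))

    if include_combined:
        X = _constraint_matrix(g, sample_ids, variables)
        Qc, R, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
        if rank < X.shape[1]:
            dependent = [variables[i] for i in piv[rank:]]
            raise OrdinationError(
                f"collinear constraint set; dependent column(s): {dependent}"
            )
        proj = Qc @ (Qc.T @ Y)
        out.append(VarianceContribution(
            "combined", 100.0 * float((proj ** 2).sum()) / total))
    return out


# ---------------------------------------------------------------------------
# CCA

@dataclass
class AxisTest:
    axis: int
    eigenvalue: float
    pseudo_f: float
    p_value: float
    n_perm: int


def _cca_eigenvalues(Q: np.ndarray, r: np.ndarray, dummies: np.ndarray,
                     n_axes: int) -> np.ndarray:
    """Constrained eigenvalues of chi-square matrix Q given group dummies."""
    Xc = dummies - r @ dummies                   # weighted centering (r sums to 1)
    Xw = np.sqrt(r)[:, None] * Xc if Xc.ndim == 2 else Xc
    Qx, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    keep = diag > (diag.max() * 1e-12 if diag.size else 0)
    Qx = Qx[:, keep]
    fitted = Qx @ (Qx.T @ Q)
    s = np.linalg.svd(fitted, compute_uv=False)
    lam = s ** 2
    return lam[:n_axes]


def cca_group_test(
    t: ASVTable,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
) -> list[AxisTest]:
    """Per-axis permutation ANOVA of a group-constrained CCA.

    The abundance table is chi-square standardized
    (Q = (P − rcᵀ)/√(rcᵀ)); constrained axes come from the
    √r-weighted regression of Q on dummy-coded groups followed by singular
    decomposition.  Each axis's eigenvalue is compared with its null
    distribution under random relabelling of the groups; the number of
    constrained axes equals (number of groups − 1).
    """
    labels = labels.loc[t.sample_ids]
    groups = labels.unique().tolist()
    counts_per = labels.value_counts()
    if (counts_per == 0).any() or len(groups) < 2:
        raise OrdinationError("need ≥2 non-empty groups")
    if (counts_per == 1).any():
        warnings.warn(
            f"group(s) with a single sample: {counts_per[counts_per == 1].index.tolist()}",
            stacklevel=2,
        )

    F = t.counts.to_numpy(dtype=float).T          # samples × taxa
    keep_taxa = F.sum(axis=0) > 0
    keep_samples = F.sum(axis=1) > 0
    if not keep_samples.all():
        raise OrdinationError("all-zero sample row(s) in abundance table")
    F = F[:, keep_taxa]

    total = F.sum()
    P = F / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)

    dummies = pd.get_dummies(labels).to_numpy(dtype=float)
    n_axes = len(groups) - 1
    lam_obs = _cca_eigenvalues(Q, r, dummies, n_axes)

    total_inertia = float((Q ** 2).sum())
    resid = total_inertia - float(lam_obs.sum())
    df_res = len(t.sample_ids) - len(groups)
    denom = resid / df_res if df_res > 0 else np.nan
    pseudo_f = lam_obs / denom

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_axes, dtype=int)
    idx = np.arange(len(t.sample_ids))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        lam_p = _cca_eigenvalues(Q, r, dummies[perm], n_axes)
        exceed += lam_p >= lam_obs
    p = (1 + exceed) / (n_perm + 1)

    return [
        AxisTest(i + 1, float(lam_obs[i]), float(pseudo_f[i]), float(p[i]), n_perm)
        for i in range(n_axes)
    ]
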