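"""Multivariate time-series modeling by PCNM-constrained redundancy analysis.

Principal Coordinates of Neighbour Matrices (PCNM, also called dbMEM)
turns the sampling-time vector into a set of orthogonal, sine-wave-like
temporal eigenfunctions spanning all resolvable frequencies: Euclidean
distances between sampling times are truncated at the largest gap between
adjacent samples (distances beyond it are set to four times the
truncation), the truncated matrix is Gower-centered and
eigen-decomposed, and the eigenvectors with positive eigenvalues are the
temporal predictors — the first models the longest temporal frequency.

A parsimonious subset of PCNMs is chosen by forward selection with the
double stopping rule (per-variable permutation significance plus the
global adjusted R-squared ceiling), and the Hellinger-transformed
community matrix is regressed on the selected PCNMs.  Redundancy
analysis (RDA) — a PCA of the fitted values — yields orthogonal
canonical axes, each a modeled temporal pattern of a species group; the
number of interpretable temporal scales is the number of axes that
survive sequential permutation tests, and the linear-combination (lc)
site scores of each axis trace its modeled pattern through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh, qr, svd

from .io import CommunityTimeSeries

__all__ = [
    "PCNMBasis",
    "RDAModel",
    "ForwardSelection",
    "build_pcnm",
    "hellinger",
    "forward_select",
    "fit_rda",
    "test_axes",
    "lc_scores",
]

#: relative eigenvalue cutoff below which a PCNM eigenvalue counts as zero
EIGEN_TOLERANCE = 1e-8


@dataclass
class PCNMBasis:
    """Positive-eigenvalue temporal eigenfunctions of the truncated
    time-distance matrix, in decreasing eigenvalue order."""

    times: np.ndarray
    truncation: float
    eigenvalues: np.ndarray
    vectors: np.ndarray  # (n_steps, k), columns orthonormal

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.vectors, columns=[f"PCNM{i+1}" for i in range(self.k)]
        )
        df.insert(0, "time", self.times)
        return df


@dataclass
class ForwardSelection:
    """Outcome of the double-stopping forward selection."""

    selected: list[int]        # 0-based PCNM indices, in selection order
    r2: float                  # raw R^2 of the selected model
    adj_r2: float              # Ezekiel-adjusted R^2 of the selected model
    global_r2: float
    global_adj_r2: float
    global_p: float
    pvalues: list[float] = field(default_factory=list)  # per selected variable


@dataclass
class RDAModel:
    """Fitted redundancy analysis."""

    canonical_eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    total_variance: float
    variance_fraction: np.ndarray    # canonical eigenvalue / total variance
    lc: np.ndarray                   # (n_steps, n_axes) lc site scores
    species_scores: np.ndarray       # (n_species, n_axes) loadings
    X: np.ndarray                    # predictor matrix used
    selected_pcnms: list[int] | None = None
    adjusted_r2: float | None = None
    axis_pvalues: np.ndarray | None = None
    n_significant: int | None = None

    @property
    def r2(self) -> float:
        return float(self.canonical_eigenvalues.sum() / self.total_variance)


def build_pcnm(times: np.ndarray) -> PCNMBasis:
    """Construct the PCNM basis from a strictly monotonic time vector.

    Truncation threshold t = the largest distance between temporally
    adjacent points (the minimal choice keeping the series connected);
    larger distances are replaced by 4t.  The Gower-centered matrix
    -D^2/2 is eigen-decomposed and eigenvectors with eigenvalues above
    ``EIGEN_TOLERANCE * max eigenvalue`` are returned, unit-norm, signs
    fixed so each vector's first nonzero entry is positive.
    """
    t = np.asarray(times, dtype=float)
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 time points")
    if len(np.unique(t)) != n:
        raise ValueError("duplicate times; preprocess (collapse equal ages) first")
    D = np.abs(t[:, None] - t[None, :])
    thresh = np.abs(np.diff(t)).max()
    D = np.where(D > thresh, 4.0 * thresh, D)

    A = -0.5 * D**2
    row = A.mean(axis=1, keepdims=True)
    G = A - row - row.T + A.mean()
    G = (G + G.T) / 2.0

    vals, vecs = eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > EIGEN_TOLERANCE * vals[0]
    vals, vecs = vals[keep], vecs[:, keep]
    for j in range(vecs.shape[1]):
        nz = np.flatnonzero(np.abs(vecs[:, j]) > 1e-12)
        if nz.size and vecs[nz[0], j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PCNMBasis(t, float(thresh), vals, vecs)


def hellinger(cts: CommunityTimeSeries | np.ndarray) -> np.ndarray:
    """Hellinger transform: square root of row-wise relative abundances.

    Every output row has unit Euclidean norm, which makes Euclidean-based
    ordination (RDA) appropriate for community composition data.
    """
    Y = cts.abundance if isinstance(cts, CommunityTimeSeries) else np.asarray(cts, float)
    if (Y < 0).any():
        raise ValueError("negative abundances")
    sums = Y.sum(axis=1)
    if (sums == 0).any():
        step = int(np.argmax(sums == 0))
        raise ValueError(f"all-zero composition at time step {step}")
    return np.sqrt(Y / sums[:, None])


def _adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel correction for m explanatory variables on n samples."""
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _orthonormal_projection_r2(V: np.ndarray, Yc: np.ndarray, ss_total: float) -> float:
    return float(np.sum((V.T @ Yc) ** 2) / ss_total)


def forward_select(
    Y: np.ndarray,
    basis: PCNMBasis,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> ForwardSelection:
    """Forward selection of PCNM variables with the double stopping rule.

    First the global model (all PCNMs) is permutation-tested; if it is not
    significant at ``alpha`` the selection is empty.  Otherwise variables
    are added greedily by R-squared gain, and addition stops as soon as the
    candidate's permutation p-value exceeds ``alpha`` or the cumulative
    adjusted R-squared of the selection exceeds the global adjusted
    R-squared.  p-values are ``(b + 1) / (n_perm + 1)``.  Deterministic
    given ``seed``.
    """
    Y = np.asarray(Y, dtype=float)
    V = basis.vectors
    n = Y.shape[0]
    if V.shape[0] != n:
        raise ValueError(f"Y has {n} rows but basis has {V.shape[0]}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    Yc = Y - Y.mean(axis=0)
    ss_total = float(np.sum(Yc**2))
    if ss_total == 0:
        raise ValueError("Y has zero variance")
    k = V.shape[1]
    global_r2 = _orthonormal_projection_r2(V, Yc, ss_total)
    global_adj = _adjusted_r2(global_r2, n, k)

    # global permutation test on R^2
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _orthonormal_projection_r2(V, Yc[perm], ss_total) >= global_r2:
            exceed += 1
    global_p = (exceed + 1) / (n_perm + 1)
    if global_p > alpha:
        return ForwardSelection([], 0.0, 0.0, global_r2, global_adj, global_p)

    selected: list[int] = []
    pvalues: list[float] = []
    remaining = np.ones(k, dtype=bool)
    R = Yc.copy()          # residual of Y on the current selection
    ss_model = 0.0
    while remaining.any():
        gains = np.sum((V[:, remaining].T @ R) ** 2, axis=1)
        idx_rem = np.flatnonzero(remaining)
        # ties broken toward the lower PCNM index (longer period)
        best_local = int(np.argmax(gains))
        j = int(idx_rem[best_local])
        gain = float(gains[best_local])

        # candidate permutation test: permute reduced-model residual rows
        v = V[:, j]
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        null_gain = np.sum((v[perms] @ R) ** 2, axis=1)
        p = (int(np.sum(null_gain >= gain)) + 1) / (n_perm + 1)
        cand_adj = _adjusted_r2((ss_model + gain) / ss_total, n, len(selected) + 1)
        if p > alpha or cand_adj > global_adj:
            break
        selected.append(j)
        pvalues.append(p)
        remaining[j] = False
        ss_model += gain
        R = R - np.outer(v, v @ R)

    r2 = ss_model / ss_total
    return ForwardSelection(
        selected, float(r2), _adjusted_r2(r2, n, len(selected)),
        global_r2, global_adj, global_p, pvalues,
    )


def _projector(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(X); raises on rank deficiency."""
    X = np.asarray(X, dtype=float)
    Q, Rm, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rm))
    rank = int(np.sum(diag > max(X.shape) * np.finfo(float).eps * diag[0]))
    if rank < X.shape[1]:
        bad = sorted(piv[rank:].tolist())
        raise ValueError(f"rank-deficient X; collinear columns {bad}")
    return Q


def fit_rda(Y: np.ndarray, X: np.ndarray) -> RDAModel:
    """Redundancy analysis of Y (rows = time steps) on predictors X.

    Y and X are centered column-wise (the regression carries an implicit
    intercept); the fitted values Yhat = projection of centered Y onto
    span(centered X) are decomposed by SVD.  Canonical eigenvalues are
    squared singular values / (n - 1); variance fractions are relative to
    the total variance of centered Y, so canonical plus residual
    eigenvalues sum to the total.  lc site scores are the projections of
    Yhat on the axes; species scores are the right singular vectors.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    Q = _projector(X - X.mean(axis=0))
    Yc = Y - Y.mean(axis=0)
    Yhat = Q @ (Q.T @ Yc)

    U, s, Wt = svd(Yhat, full_matrices=False)
    n_axes = int(np.sum(s**2 > EIGEN_TOLERANCE * max(s[0] ** 2, 1e-300)))
    n_axes = min(n_axes, X.shape[1])
    U, s, Wt = U[:, :n_axes], s[:n_axes], Wt[:n_axes]
    can_eig = s**2 / (n - 1)

    Yres = Yc - Yhat
    res_s = svd(Yres, compute_uv=False)
    res_eig = res_s**2 / (n - 1)
    total = float(np.sum(Yc**2) / (n - 1))

    lc = U * s  # = Yhat @ W
    # deterministic axis orientation: largest-|loading| species positive
    for a in range(n_axes):
        jmax = int(np.argmax(np.abs(Wt[a])))
        if Wt[a, jmax] < 0:
            Wt[a] = -Wt[a]
            lc[:, a] = -lc[:, a]
    return RDAModel(
        canonical_eigenvalues=can_eig,
        residual_eigenvalues=res_eig,
        total_variance=total,
        variance_fraction=can_eig / total,
        lc=lc,
        species_scores=Wt.T,
        X=X,
    )


def test_axes(
    model: RDAModel,
    Y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Sequential permutation tests of the canonical axes.

    Axis a is tested marginally on the residual of Y after removing the
    fitted components of the preceding axes: rows of that residual are
    permuted, the RDA refitted, and the first canonical eigenvalue of the
    permuted fit compared with axis a's eigenvalue;
    p = (b + 1) / (n_perm + 1).  Scanning from axis 1, axes are declared
    significant while p <= alpha; the scan stops at the first
    non-significant axis.  Fills ``model.axis_pvalues`` and
    ``model.n_significant`` and returns them.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = Y.shape[0]
    Q = _projector(X - X.mean(axis=0))
    Yc = Y - Y.mean(axis=0)

    n_axes = len(model.canonical_eigenvalues)
    pvals = np.full(n_axes, np.nan)
    n_sig = 0
    Ya = Yc.copy()
    for a in range(n_axes):
        Yhat_a = Q @ (Q.T @ Ya)
        Ua, sa, Wa = svd(Yhat_a, full_matrices=False)
        stat = sa[0] ** 2
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            M = Q.T @ Ya[perm]
            s0 = svd(M, compute_uv=False)[0]
            if s0**2 >= stat:
                exceed += 1
        pvals[a] = (exceed + 1) / (n_perm + 1)
        if pvals[a] <= alpha:
            n_sig += 1
        else:
            break
        # remove this axis' fitted component before testing the next
        Ya = Ya - np.outer(Ua[:, 0] * sa[0], Wa[0])
    model.axis_pvalues = pvals
    model.n_significant = n_sig
    return pvals, n_sig


def lc_scores(model: RDAModel) -> pd.DataFrame:
    """lc site scores per axis (columns RDA1, RDA2, ... by eigenvalue).

    Each column is a linear combination of the predictors, has zero mean,
    and the columns are mutually orthogonal.
    """
    return pd.DataFrame(
        model.lc, columns=[f"RDA{a+1}" for a in range(model.lc.shape[1])]
    )
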