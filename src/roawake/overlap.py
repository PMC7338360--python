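"""State specificity of activation maps: Jaccard distances and PERMANOVA.

Episode heatmaps are compared with the weighted Jaccard similarity
``J(x, y) = sum_i min(x_i, y_i) / sum_i max(x_i, y_i)`` (0 = no overlap,
1 = identical activation); ``d = 1 - J`` is the Jaccard distance.  Whether
episodes of the same behavioural state are more alike than episodes of
different states is tested with PERMANOVA (permutational multivariate
analysis of variance) on the distance matrix, with the per-episode mean
activation entered first as a covariate so the state effect is conditional
on the overall activation level.  Only fields of view contributing at least
eight episodes are analysed.

The partitioning follows the distance-based linear-model formulation: with
the Gower-centred matrix ``G = C (-D^2/2) C`` and hat matrices ``H`` of the
nested design matrices, a term's sum of squares is the increment in
``tr(H G)``, and the state pseudo-F is the term mean square over the
residual mean square.  p-values come from permutations; by default the raw
state labels are permuted freely (``method='labels'``); Freedman-Lane
permutation of covariate-adjusted residuals is available
(``method='residual'``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MIN_EPISODES = 8


@dataclass
class EpisodeHeatmapSet:
    """Flattened episode heatmaps with state labels and activation covariate.

    ``heatmaps`` has one row per episode; ``mean_activation`` defaults to the
    row means.
    """

    heatmaps: np.ndarray
    states: np.ndarray
    mean_activation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heatmaps = np.atleast_2d(np.asarray(self.heatmaps, dtype=float))
        self.states = np.asarray(self.states)
        if self.heatmaps.shape[0] != self.states.size:
            raise ValueError("one state label per episode required")
        if self.mean_activation is None:
            self.mean_activation = self.heatmaps.mean(axis=1)
        else:
            self.mean_activation = np.asarray(self.mean_activation,
                                              dtype=float)

    @property
    def n_episodes(self) -> int:
        return self.heatmaps.shape[0]


@dataclass
class PermanovaResult:
    R2: float
    p_value: float
    pseudo_F: float
    n_permutations: int
    seed: int
    df_state: int
    df_resid: int
    covariate_R2: float = float("nan")
    method: str = "labels"

    def summary(self) -> str:
        return (f"PERMANOVA (state factor, {self.method} permutations)\n"
                f"  pseudo-F = {self.pseudo_F:.4f} "
                f"(df {self.df_state}, {self.df_resid})\n"
                f"  R^2      = {self.R2:.4f}\n"
                f"  p        = {self.p_value:.4g} "
                f"({self.n_permutations} permutations, seed {self.seed})")


def jaccard_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Weighted Jaccard similarity of two non-negative pixel vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("vectors must be non-negative")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        warnings.warn("Jaccard similarity undefined for two all-zero "
                      "vectors", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.minimum(x, y).sum() / denom)


def distance_matrix(heatmap_set: EpisodeHeatmapSet,
                    enforce_min_episodes: bool = True) -> np.ndarray:
    """Pairwise Jaccard distances ``d = 1 - J`` between episode heatmaps."""
    n = heatmap_set.n_episodes
    if enforce_min_episodes and n < MIN_EPISODES:
        raise ValueError(
            f"{n} episodes < {MIN_EPISODES}: only fields of view with eight "
            "or more episodes are analysed")
    H = heatmap_set.heatmaps
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        hi = H[i]
        mins = np.minimum(hi[None, :], H[i + 1:]).sum(axis=1)
        maxs = np.maximum(hi[None, :], H[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.where(maxs > 0, mins / maxs, np.nan)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


# --------------------------------------------------------------- PERMANOVA

def _gower_center(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    A = -0.5 * D ** 2
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


def _dummies(states: np.ndarray) -> np.ndarray:
    levels, codes = np.unique(states, return_inverse=True)
    X = np.zeros((states.size, levels.size - 1))
    for j in range(1, levels.size):
        X[codes == j, j - 1] = 1.0
    return X


def _pseudo_f(ss_term, ss_resid, df_term: int, df_resid: int,
              ss_total: float):
    """Term MS over residual MS; an (almost) zero residual yields +inf."""
    eps = 1e-12 * max(abs(ss_total), 1.0)
    with np.errstate(divide="ignore"):
        return np.where(np.asarray(ss_resid) > eps,
                        (ss_term / df_term) /
                        (np.maximum(ss_resid, eps) / df_resid),
                        np.inf)[()]


def _hat_trace(X: np.ndarray, G: np.ndarray) -> float:
    """tr(H G) with H the hat matrix of X (rank-safe via QR/SVD)."""
    Q = np.linalg.qr(X)[0]
    return float(np.einsum("ij,ij->", Q, G @ Q))


def permanova(D: np.ndarray, states: np.ndarray,
              covariate: np.ndarray | None = None,
              n_permutations: int = 999, seed: int = 0,
              method: str = "labels") -> PermanovaResult:
    """PERMANOVA for the state factor, sequential after the covariate.

    Parameters
    ----------
    D : (n, n) symmetric distance matrix.
    states : state label per episode (>= 2 levels, each with >= 2 episodes).
    covariate : optional per-episode scalar, entered before the state factor.
    method : 'labels' (free permutation of state labels) or 'residual'
        (Freedman-Lane permutation of covariate-adjusted residuals).
    """
    D = np.asarray(D, dtype=float)
    states = np.asarray(states)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("D must be a symmetric square matrix")
    levels, counts = np.unique(states, return_counts=True)
    if levels.size < 2:
        raise ValueError("need >= 2 state levels")
    if (counts < 2).any():
        raise ValueError("each state level needs >= 2 episodes")
    if method not in ("labels", "residual"):
        raise ValueError("method must be 'labels' or 'residual'")

    ones = np.ones((n, 1))
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float).reshape(n, 1)
        if np.ptp(cov) == 0:
            cov = None  # constant covariate: one-factor PERMANOVA
    else:
        cov = None
    X_nuis = ones if cov is None else np.hstack([ones, cov])
    X_state = _dummies(states)
    X_full = np.hstack([X_nuis, X_state])

    G = _gower_center(D)
    ss_total = float(np.trace(G))
    tr_nuis = _hat_trace(X_nuis, G)
    tr_full = _hat_trace(X_full, G)
    df_state = levels.size - 1
    df_resid = n - np.linalg.matrix_rank(X_full)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_state = tr_full - tr_nuis
    ss_resid = max(ss_total - tr_full, 0.0)
    F_obs = _pseudo_f(ss_state, ss_resid, df_state, df_resid, ss_total)
    R2 = min(max(ss_state / ss_total, 0.0), 1.0)
    cov_R2 = (tr_nuis / ss_total) if cov is not None else float("nan")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    if method == "labels":
        # permute the state design rows; nuisance columns stay in place
        Xp = np.empty((n_permutations, n, X_full.shape[1]))
        Xp[:, :, :X_nuis.shape[1]] = X_nuis
        Xp[:, :, X_nuis.shape[1]:] = X_state[perms]
        Q = np.linalg.qr(Xp)[0]
        GQ = np.einsum("ij,bjk->bik", G, Q)
        tr_full_p = np.einsum("bij,bij->b", Q, GQ)
        F_perm = _pseudo_f(tr_full_p - tr_nuis,
                           np.maximum(ss_total - tr_full_p, 0.0),
                           df_state, df_resid, ss_total)
    else:
        R = G - _project(X_nuis, G)
        F_perm = np.empty(n_permutations)
        for b, p in enumerate(perms):
            Gp = R[np.ix_(p, p)]
            tr_n = _hat_trace(X_nuis, Gp)
            tr_f = _hat_trace(X_full, Gp)
            F_perm[b] = _pseudo_f(tr_f - tr_n,
                                  max(np.trace(Gp) - tr_f, 0.0),
                                  df_state, df_resid, ss_total)
    p_value = (1 + int(np.sum(F_perm >= F_obs))) / (1 + n_permutations)
    return PermanovaResult(R2=float(R2), p_value=float(p_value),
                           pseudo_F=float(F_obs),
                           n_permutations=n_permutations, seed=seed,
                           df_state=df_state, df_resid=df_resid,
                           covariate_R2=float(cov_R2), method=method)


def _project(X: np.ndarray, G: np.ndarray) -> np.ndarray:
    Q = np.linalg.qr(X)[0]
    HG = Q @ (Q.T @ G)
    return HG + HG.T - Q @ (Q.T @ HG @ Q) @ Q.T


def analyze_fov(heatmap_set: EpisodeHeatmapSet, n_permutations: int = 999,
                seed: int = 0, method: str = "labels") -> PermanovaResult:
    """Distance matrix + PERMANOVA for one field of view."""
    D = distance_matrix(heatmap_set)
    return permanova(D, heatmap_set.states, heatmap_set.mean_activation,
                     n_permutations=n_permutations, seed=seed, method=method)
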