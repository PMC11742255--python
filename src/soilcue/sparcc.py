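"""SparCC-style compositionality-robust correlation inference.

Sequencing counts are compositional: only relative abundances are observed,
so ordinary Pearson correlations between taxa are distorted by the closure to
a fixed read depth. SparCC works instead from log-ratio variances

    t_ij = Var[ log(x_i / x_j) ]  =  ω_i² + ω_j² − 2 ρ_ij ω_i ω_j,

which are invariant to the per-sample normalisation. Under a sparsity
assumption (most true basis correlations ρ_ij are near zero) the basis
variances ω_i² are identifiable from the row sums of T by solving the linear
system ((D−2)·I + 𝟙𝟙ᵀ)·ω² = T·𝟙, after which each correlation follows from
the displayed identity. Strongly correlated pairs — which violate the
sparsity assumption — are excluded from the variance system one at a time and
the system re-solved, up to a fixed number of rounds.

The full estimator resamples the fraction matrix from a per-sample
Dirichlet(counts + 1) posterior and reports the element-wise median across
iterations; pseudo P-values come from a permutation null in which each
taxon's counts are shuffled independently across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import OtuTable

#: |basis correlation| above which a pair is excluded from the variance system.
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_MAX_EXCLUSION_ROUNDS = 10
DEFAULT_N_ITERATIONS = 20
DEFAULT_N_BOOTSTRAPS = 100
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class CorrelationEstimate:
    """Symmetric correlation matrix over taxa, with optional pseudo P-values."""

    taxon_ids: list[str]
    r_matrix: np.ndarray
    pseudo_p_matrix: np.ndarray | None = None
    n_iterations: int = DEFAULT_N_ITERATIONS
    n_bootstraps: int = 0

    def __post_init__(self) -> None:
        r = self.r_matrix
        if r.shape[0] != r.shape[1] or r.shape[0] != len(self.taxon_ids):
            raise ValueError("r_matrix shape does not match taxon_ids")
        if not np.allclose(r, r.T):
            raise ValueError("r_matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("r_matrix must have unit diagonal")


def _fraction_matrix(counts: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Point-estimate fractions (samples × taxa) with pseudocount zero handling."""
    a = counts.T.astype(float) + pseudocount
    return a / a.sum(axis=1, keepdims=True)


def _dirichlet_fractions(
    counts: np.ndarray, rng: np.random.Generator, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """One Dirichlet(counts + pseudocount) posterior draw of the fraction matrix."""
    g = rng.gamma(shape=counts.T.astype(float) + pseudocount)
    return g / g.sum(axis=1, keepdims=True)


def log_ratio_variance_matrix(fractions: np.ndarray) -> np.ndarray:
    """T with t_ij = Var[log(x_i/x_j)] across samples (samples × taxa input).

    Symmetric with a zero diagonal. Computed from the covariance of log
    fractions: t_ij = c_ii + c_jj − 2 c_ij.
    """
    fractions = np.asarray(fractions, dtype=float)
    n, d = fractions.shape
    if d < 2:
        raise ValueError("need at least 2 taxa")
    if n < 4:
        raise ValueError("need at least 4 samples to estimate log-ratio variances")
    c = np.cov(np.log(fractions), rowvar=False)
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2 * c
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlations(
    T: np.ndarray,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusion_rounds: int = DEFAULT_MAX_EXCLUSION_ROUNDS,
) -> np.ndarray:
    """Solve for basis correlations from a log-ratio variance matrix.

    Solves the sparsity-assumption linear system for the basis variances,
    then iteratively excludes the single most-correlated pair exceeding
    ``exclusion_threshold`` from the system and re-solves, for at most
    ``max_exclusion_rounds`` rounds. For exactly three taxa with no
    exclusions the solution reduces to the closed form
    ω_i² = (t_ij + t_ik − t_jk) / 2.
    """
    T = np.asarray(T, dtype=float)
    d = T.shape[0]
    if d < 3:
        raise ValueError("basis variances are underdetermined with fewer than 3 taxa")

    # M ω² = T·1 with M = (D−2)·I + 𝟙𝟙ᵀ; excluding pair (i,j) removes t_ij
    # from both row sums and the pair's coupling from M.
    M = np.ones((d, d)) + (d - 2) * np.eye(d)
    rowsum = T.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)

    def solve_rho() -> np.ndarray:
        try:
            w2 = np.linalg.solve(M, rowsum)
        except np.linalg.LinAlgError:
            w2 = np.linalg.lstsq(M, rowsum, rcond=None)[0]
        w2 = np.maximum(w2, 1e-12)
        w = np.sqrt(w2)
        rho = (w2[:, None] + w2[None, :] - T) / (2 * np.outer(w, w))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho

    rho = solve_rho()
    for _ in range(max_exclusion_rounds):
        masked = np.where(excluded, 0.0, np.abs(rho))
        np.fill_diagonal(masked, 0.0)
        # a taxon must keep at least two un-excluded partners or the
        # variance system degenerates
        saturated = M.diagonal() <= 2
        masked[saturated, :] = 0.0
        masked[:, saturated] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        rowsum[i] -= T[i, j]
        rowsum[j] -= T[i, j]
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] = M[j, i] = 0
        rho = solve_rho()
    return rho


def sparcc(
    table: OtuTable | np.ndarray,
    n_iter: int = DEFAULT_N_ITERATIONS,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusion_rounds: int = DEFAULT_MAX_EXCLUSION_ROUNDS,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    taxon_ids: list[str] | None = None,
) -> CorrelationEstimate:
    """SparCC correlation estimate: median of ``n_iter`` Dirichlet resamples.

    Each iteration draws a fraction matrix from the per-sample
    Dirichlet(counts + pseudocount) posterior, estimates basis correlations,
    and the element-wise median across iterations is reported. With
    ``n_iter=1`` this reduces to a single basis-correlation estimate on one
    resample. Deterministic at a fixed seed.
    """
    if isinstance(table, OtuTable):
        counts = table.counts.values
        taxon_ids = taxon_ids or table.taxon_ids
    else:
        counts = np.asarray(table)
        taxon_ids = taxon_ids or [f"taxon_{i}" for i in range(counts.shape[0])]
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_iter, counts.shape[0], counts.shape[0]))
    for k in range(n_iter):
        frac = _dirichlet_fractions(counts, rng, pseudocount)
        T = log_ratio_variance_matrix(frac)
        estimates[k] = basis_correlations(T, exclusion_threshold, max_exclusion_rounds)
    r = np.median(estimates, axis=0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationEstimate(list(taxon_ids), r, n_iterations=n_iter)


def bootstrap_pseudo_p(
    table: OtuTable | np.ndarray,
    observed_r: np.ndarray,
    n_bootstraps: int = DEFAULT_N_BOOTSTRAPS,
    n_iter: int = DEFAULT_N_ITERATIONS,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusion_rounds: int = DEFAULT_MAX_EXCLUSION_ROUNDS,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Two-sided permutation pseudo P-values for an observed SparCC matrix.

    The null distribution is built by independently permuting each taxon's
    counts across samples (destroying all between-taxon association while
    keeping marginal abundance distributions) and re-running the estimator.
    With the add-one rule p̂_ij = (1 + #{b : |r_b| ≥ |r_obs|}) / (B + 1),
    the smallest attainable value is 1/(B+1).
    """
    counts = table.counts.values if isinstance(table, OtuTable) else np.asarray(table)
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed_r)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_bootstraps):
        perm = np.empty_like(counts)
        for i in range(counts.shape[0]):
            perm[i] = rng.permutation(counts[i])
        est = sparcc(
            perm,
            n_iter=n_iter,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
            seed=int(rng.integers(2**31)),
            pseudocount=pseudocount,
        )
        exceed += np.abs(est.r_matrix) >= abs_obs
    p = (1.0 + exceed) / (n_bootstraps + 1.0)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0)
    return p
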