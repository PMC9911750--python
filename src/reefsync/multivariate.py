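"""Multivariate community structure: zero-adjusted Bray-Curtis, NMDS,
and two-factor PERMANOVA with interaction.

The Bray-Curtis step appends a constant "dummy taxon" to every sample
before computing dissimilarities, so two samples that have both lost all
coral read as identical (d = 0) instead of undefined -- the standard
zero-adjustment for zero-inflated cover data.

NMDS minimises Kruskal stress-1 over a 2-d configuration: configuration
distances are fitted to dissimilarity ranks by isotonic (monotone)
regression with primary tie treatment, and the configuration is updated
by a Guttman majorization step with a halving line search that makes the
recorded stress non-increasing within each start. One start is seeded
from classical (metric) scaling, the rest are random; restarts stop early
once the best stress falls below the tolerance.

PERMANOVA partitions the Gower-centred distance matrix into sequential
(Type I) sums of squares for habitat, year and their interaction;
p-values come from unrestricted permutation of sample rows.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DissimilarityMatrix",
    "Ordination",
    "PermanovaResult",
    "zero_adjusted_bray_curtis",
    "nmds",
    "stress1",
    "permanova_two_way",
]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    d: np.ndarray  # square symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Ordination:
    coordinates: np.ndarray  # samples x k, centred at the origin
    stress: float  # Kruskal stress-1 of the best start
    n_restarts_used: int
    converged: bool
    stress_history: list[np.ndarray] = field(default_factory=list)


@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # index: term; columns: ss, df, pseudo_f, p
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int
    undefined: bool = False  # all samples identical: no variation to test


def zero_adjusted_bray_curtis(
    cover: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    dummy: float = 1.0,
) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities after appending a constant dummy column.

    With ``dummy`` > 0 the denominator is always positive, and all-zero
    samples are mutually identical (they share only the dummy taxon).
    """
    if isinstance(cover, pd.DataFrame):
        labels = labels or [str(i) for i in cover.index]
        cover = cover.to_numpy()
    cover = np.asarray(cover, dtype=float)
    if np.any(cover < 0):
        raise ValueError("cover values must be nonnegative")
    if dummy < 0:
        raise ValueError("dummy value must be nonnegative")
    labels = labels or [str(i) for i in range(len(cover))]
    adjusted = np.hstack([cover, np.full((cover.shape[0], 1), float(dummy))])
    d = squareform(pdist(adjusted, metric="braycurtis"))
    return DissimilarityMatrix(labels, d)


def stress1(config: np.ndarray, diss: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against condensed dissimilarities."""
    dist = pdist(config)
    dhat = _monotone_fit(dist, diss)
    denom = float(np.sum(dist**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _monotone_fit(dist: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Isotonic fit of configuration distances on dissimilarity order.

    Primary tie treatment: tied dissimilarities are ordered by their
    current configuration distances, leaving them unconstrained against
    each other.
    """
    order = np.lexsort((dist, diss))
    dhat = np.empty_like(dist)
    dhat[order] = isotonic_regression(dist[order]).x
    return dhat


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling start configuration."""
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh(g)
    idx = np.argsort(vals)[::-1][:k]
    pos = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(pos)


def _nmds_single_start(
    diss: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    n = x0.shape[0]
    x = x0 - x0.mean(axis=0)
    history = [stress1(x, diss)]
    converged = False
    for _ in range(max_iter):
        dist = pdist(x)
        dhat = _monotone_fit(dist, diss)
        # Guttman transform toward the fitted disparities
        safe = np.where(dist > 1e-12, dist, 1e-12)
        ratio = squareform(dhat / safe, checks=False)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = (b @ x) / n
        s_new = stress1(x_new, diss)
        # halving line search keeps the recorded stress monotone
        step = 1.0
        while s_new > history[-1] and step > 1e-4:
            step /= 2.0
            x_new = x + step * ((b @ x) / n - x)
            s_new = stress1(x_new, diss)
        if s_new > history[-1]:
            converged = True
            break
        x = x_new - x_new.mean(axis=0)
        history.append(s_new)
        if history[-2] - history[-1] < tol:
            converged = True
            break
    return x, history[-1], np.asarray(history), converged


def nmds(
    dm: DissimilarityMatrix,
    k: int = 2,
    restarts: int = 20,
    stress_tol: float = 0.02,
    max_iter: int = 300,
    conv_tol: float = 1e-6,
    seed: int | None = 0,
) -> Ordination:
    """Non-metric multidimensional scaling to ``k`` dimensions.

    Runs up to ``restarts`` starts (metric-scaling start first, then
    random) and keeps the lowest-stress configuration, stopping early once
    stress drops below ``stress_tol``. Non-convergence within the
    iteration cap returns the best-so-far with ``converged=False`` and a
    warning.
    """
    n = len(dm.labels)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-d NMDS")
    diss = dm.condensed()
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, bool] | None = None
    histories: list[np.ndarray] = []
    used = 0
    for start in range(max(restarts, 1)):
        x0 = (
            _classical_scaling(dm.d, k)
            if start == 0
            else rng.normal(size=(n, k))
        )
        x, s, hist, conv = _nmds_single_start(diss, x0, max_iter, conv_tol)
        histories.append(hist)
        used += 1
        if best is None or s < best[1]:
            best = (x, s, conv)
        if best[1] < stress_tol:
            break
    assert best is not None
    x, s, conv = best
    conv = conv or s < stress_tol  # stress stabilised below tolerance
    if not conv:
        warnings.warn("NMDS did not converge within the iteration cap", stacklevel=2)
    return Ordination(
        coordinates=x - x.mean(axis=0),
        stress=s,
        n_restarts_used=used,
        converged=conv,
        stress_history=histories,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred matrix G = -(I - 11'/n) D^2 (I - 11'/n) / 2."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _dummy_code(levels: np.ndarray) -> np.ndarray:
    """Drop-first treatment coding, columns for levels 2..k."""
    uniq = np.unique(levels)
    return (levels[:, None] == uniq[None, 1:]).astype(float)


def permanova_two_way(
    dm: DissimilarityMatrix,
    habitat: np.ndarray | pd.Series,
    year: np.ndarray | pd.Series | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Two-factor PERMANOVA (habitat, year, habitat x year) on a
    dissimilarity matrix.

    Sums of squares are sequential in the order habitat, year,
    interaction (equal to marginal SS for balanced designs); pseudo-F uses
    the residual mean square, and p = (1 + #{F_perm >= F_obs}) / (1 +
    n_perm) under unrestricted permutation of sample rows. Factors with a
    single level are dropped with a warning; the interaction needs
    replication within cells to be testable.
    """
    habitat = np.asarray(habitat)
    d = dm.d
    n = d.shape[0]
    if habitat.shape[0] != n:
        raise ValueError("habitat factor length does not match matrix")
    g = _gower_center(d)
    total_ss = float(np.trace(g))
    if total_ss <= 1e-12:
        warnings.warn("all samples identical: PERMANOVA undefined", stacklevel=2)
        empty = pd.DataFrame(columns=["ss", "df", "pseudo_f", "p"])
        return PermanovaResult(empty, 0.0, 0, 0.0, n_perm, undefined=True)

    terms: list[tuple[str, np.ndarray]] = []
    if len(np.unique(habitat)) > 1:
        terms.append(("habitat", _dummy_code(habitat)))
    else:
        warnings.warn("habitat has a single level: term dropped", stacklevel=2)
    if year is not None:
        year = np.asarray(year)
        if len(np.unique(year)) > 1:
            terms.append(("year", _dummy_code(year)))
        else:
            warnings.warn("year has a single level: term dropped", stacklevel=2)
    if len(terms) == 2:
        inter = (terms[0][1][:, :, None] * terms[1][1][:, None, :]).reshape(n, -1)
        cells = pd.Series(range(n)).groupby([habitat, year]).size()
        if (cells > 1).all():
            terms.append(("habitat:year", inter))
        else:
            warnings.warn(
                "interaction untestable without within-cell replication",
                stacklevel=2,
            )
    if not terms:
        raise ValueError("no testable terms")

    design = np.hstack([np.ones((n, 1))] + [x for _, x in terms])
    q_full, r = np.linalg.qr(design)
    if np.min(np.abs(np.diag(r))) < 1e-8 * np.max(np.abs(np.diag(r))):
        raise ValueError("design matrix is rank-deficient (empty cells?)")
    # column blocks of q_full span intercept, then each sequential term
    widths = [1] + [x.shape[1] for _, x in terms]
    edges = np.cumsum(widths)
    dfs = np.array([x.shape[1] for _, x in terms])
    resid_df = n - edges[-1]
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_ss(q: np.ndarray) -> np.ndarray:
        """Sequential SS per term from an (orthonormal) design basis."""
        gq = g @ q
        col = np.einsum("ij,ij->j", q, gq)  # diag of Q' G Q
        return np.array(
            [col[edges[i] : edges[i + 1]].sum() for i in range(len(terms))]
        )

    ss_obs = term_ss(q_full)
    resid_ss = total_ss - ss_obs.sum()
    f_obs = (ss_obs / dfs) / (resid_ss / resid_df)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_p = term_ss(q_full[perm])
        resid_p = total_ss - ss_p.sum()
        f_p = (ss_p / dfs) / (resid_p / resid_df)
        exceed += f_p >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    frame = pd.DataFrame(
        {"ss": ss_obs, "df": dfs, "pseudo_f": f_obs, "p": p},
        index=[name for name, _ in terms],
    )
    return PermanovaResult(frame, float(resid_ss), int(resid_df), total_ss, n_perm)
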