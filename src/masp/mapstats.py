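"""Statistics on protein distribution maps.

Four analyses operate on the generated maps:

* **map correlation** — Pearson r (with a two-sided p from the exact t
  transform, df = n−2) or cosine similarity between two maps over their
  pairwise-complete wells;
* **Bonferroni r-threshold** — the smallest |r| significant at level alpha
  after correcting for the number of map comparisons, obtained by inverting
  the t transform (with ~200 locations and ~5000 comparisons this lands near
  r ≈ 0.3, the usual rule of thumb for these datasets);
* **map clustering** — spectral clustering on the affinity (1 + r)/2 with
  eigengap selection of k, to group proteins with similar regional patterns;
* **regional-pattern detection** — permutation-tested Moran's I (rook
  adjacency on the occupied wells) with Benjamini-Hochberg FDR control, to
  flag proteins whose distribution is spatially non-random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .gridio import QuantMatrix, SpatialGrid, match_samples
from .mapping import ProteinMap

logger = logging.getLogger(__name__)

MIN_PAIRS_PEARSON = 3
MIN_PAIRS_COSINE = 1
MIN_OBS_PATTERN = 8


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    protein_a: str
    protein_b: str
    method: str  # "pearson" | "cosine"
    r: float
    n_pairs: int
    p_raw: float | None = None  # pearson only
    significant: bool | None = None


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the exact t transform, df = n−2."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def _pairwise_complete(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = ~np.isnan(a) & ~np.isnan(b)
    return a[mask], b[mask]


def map_correlation(
    a: ProteinMap,
    b: ProteinMap,
    method: str = "pearson",
    n_tests: int = 1,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlate two maps over their jointly observed wells.

    Pearson needs ≥3 joint wells, cosine ≥1.  The significance flag applies a
    Bonferroni correction over ``n_tests`` comparisons (Pearson only).
    """
    if a.grid.wells != b.grid.wells or a.grid.n_rows != b.grid.n_rows:
        raise ValueError("maps must share one grid")
    x, y = _pairwise_complete(a.values_vector(), b.values_vector())
    return _correlate_vectors(a.protein_id, b.protein_id, x, y, method, n_tests, alpha)


def _correlate_vectors(
    id_a: str, id_b: str, x: np.ndarray, y: np.ndarray, method: str, n_tests: int, alpha: float
) -> CorrelationResult:
    n = len(x)
    if method == "pearson":
        if n < MIN_PAIRS_PEARSON:
            raise ValueError(
                f"{id_a} vs {id_b}: only {n} jointly observed wells; "
                f"pearson needs >= {MIN_PAIRS_PEARSON}"
            )
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise ValueError(f"{id_a} vs {id_b}: constant map, pearson undefined")
        r = float(np.clip(((x - x.mean()) * (y - y.mean())).sum() / (n * sx * sy), -1.0, 1.0))
        p = _pearson_p(r, n)
        return CorrelationResult(id_a, id_b, "pearson", r, n, p, bool(p * n_tests <= alpha))
    if method == "cosine":
        if n < MIN_PAIRS_COSINE:
            raise ValueError(f"{id_a} vs {id_b}: no jointly observed wells")
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError(f"{id_a} vs {id_b}: zero-norm map, cosine undefined")
        r = float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
        return CorrelationResult(id_a, id_b, "cosine", r, n)
    raise ValueError(f"unknown method {method!r}; use 'pearson' or 'cosine'")


def bonferroni_r_threshold(n_obs: int, n_tests: int, alpha: float = 0.05) -> float:
    """Smallest |r| whose two-sided p (t transform, df = n_obs−2) is ≤ alpha/n_tests.

    Monotone increasing in ``n_tests`` and decreasing in ``n_obs``.
    """
    if n_obs < 4:
        raise ValueError("n_obs must be >= 4 for a meaningful threshold (df >= 2)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n_obs - 2
    t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n_tests), df)
    return float(t_crit / np.sqrt(t_crit * t_crit + df))


def correlate_all(
    q: QuantMatrix,
    g: SpatialGrid,
    target: str,
    method: str = "pearson",
    alpha: float = 0.05,
) -> tuple[list[CorrelationResult], float]:
    """Correlate one protein's map against every other protein's map.

    Returns results ranked by descending r plus the median r over all
    comparisons.  Significance flags use the Bonferroni threshold with
    ``n_tests`` = number of comparisons attempted.  Proteins with too few
    jointly observed wells are skipped with a warning.
    """
    if target not in set(q.feature_ids):
        raise KeyError(f"target protein {target!r} not in matrix")
    qg = match_samples(q, g)
    vals = qg.values.to_numpy()
    cols = list(qg.values.columns)
    ti = cols.index(target)
    tvec = vals[:, ti]
    n_tests = len(cols) - 1
    results: list[CorrelationResult] = []
    skipped = []
    for j, pid in enumerate(cols):
        if j == ti:
            continue
        x, y = _pairwise_complete(tvec, vals[:, j])
        try:
            results.append(_correlate_vectors(target, pid, x, y, method, n_tests, alpha))
        except ValueError:
            skipped.append(pid)
    if skipped:
        logger.warning(
            "%d protein(s) skipped in correlate_all (insufficient overlap or "
            "zero variance), e.g. %s",
            len(skipped),
            skipped[:3],
        )
    if not results:
        raise ValueError("no protein could be correlated with the target")
    results.sort(key=lambda cr: cr.r, reverse=True)
    median_r = float(np.median([cr.r for cr in results]))
    return results, median_r


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: dict[str, int]
    k: int
    affinity_method: str
    eigengap_scores: list[float] = field(default_factory=list)


def _affinity_matrix(maps: list[ProteinMap]) -> pd.DataFrame:
    """(1 + pairwise-complete Pearson r) / 2 between vectorized maps."""
    df = pd.DataFrame(
        {m.protein_id: m.values_vector() for m in maps}
    )
    if (df.std(skipna=True) == 0).all():
        raise ValueError("all maps are constant; affinity undefined")
    r = df.corr(method="pearson", min_periods=MIN_PAIRS_PEARSON)
    aff = (1.0 + r) / 2.0
    np.fill_diagonal(aff.values, 1.0)
    return aff.fillna(0.0)  # no usable overlap -> no similarity evidence


def _eigengap_k(aff: np.ndarray, k_max: int) -> tuple[int, list[float]]:
    """Pick k by the largest gap in the normalized-Laplacian spectrum."""
    d = aff.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    lap = np.eye(len(aff)) - d_inv_sqrt[:, None] * aff * d_inv_sqrt[None, :]
    eig = np.sort(np.linalg.eigvalsh(lap))
    gaps = [float(eig[k] - eig[k - 1]) for k in range(1, min(k_max, len(eig) - 1) + 1)]
    # gap after the k-th smallest eigenvalue argues for k clusters; k >= 2
    best_k = int(np.argmax(gaps[1:]) + 2) if len(gaps) > 1 else 1
    return best_k, gaps


def cluster_maps(
    maps: list[ProteinMap], k: int | str = "auto", seed: int = 0, k_max: int = 10
) -> ClusterResult:
    """Group maps with similar regional patterns by spectral clustering.

    The affinity is (1 + Pearson r)/2 on the vectorized maps
    (pairwise-complete), making the grouping invariant to per-map affine
    rescaling.  With ``k='auto'`` the number of clusters is chosen by the
    largest eigengap of the normalized Laplacian.  Deterministic given seed.
    """
    from sklearn.cluster import SpectralClustering

    if len(maps) < 2:
        raise ValueError("need at least 2 maps to cluster")
    ids = [m.protein_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids among maps")
    aff = _affinity_matrix(maps)
    A = aff.to_numpy()
    auto_k, gaps = _eigengap_k(A, min(k_max, len(maps) - 1))
    if k == "auto":
        k = auto_k
    k = int(k)
    if not 1 <= k <= len(maps):
        raise ValueError(f"k={k} out of range [1, {len(maps)}]")
    if k == 1:
        labels = np.zeros(len(maps), dtype=int)
    else:
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans"
        )
        labels = sc.fit_predict(A)
    return ClusterResult(
        labels=dict(zip(ids, (int(l) for l in labels))),
        k=k,
        affinity_method="(1+pearson)/2",
        eigengap_scores=gaps,
    )


# ---------------------------------------------------------------------------
# regional (non-random) pattern detection: permutation Moran's I
# ---------------------------------------------------------------------------


@dataclass
class PatternResult:
    protein_id: str
    statistic: float  # Moran's I
    p_perm: float
    q_value: float
    n_permutations: int
    seed: int
    n_observed: int = 0


def rook_adjacency(g: SpatialGrid) -> sp.csr_matrix:
    """Binary rook (4-neighbour) adjacency among occupied wells, row-major order."""
    wells = g.sorted_wells()
    index = {w: i for i, w in enumerate(wells)}
    rows, cols = [], []
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            nb = (r + dr, c + dc)
            if nb in index:
                j = index[nb]
                rows += [i, j]
                cols += [j, i]
    n = len(wells)
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def morans_i(values: np.ndarray, W: sp.spmatrix) -> float:
    """Moran's I = (n/S0) · (zᵀWz)/(zᵀz) with z the centered values."""
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    s0 = float(W.sum())
    if s0 == 0:
        raise ValueError("no adjacent well pairs")
    return float(len(values) / s0 * (z @ (W @ z)) / denom)


def _moran_permutation_p(
    z: np.ndarray, W_dense: np.ndarray, s0: float, B: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed I and one-sided permutation p = (1 + #{I_perm >= I_obs})/(B+1)."""
    n = len(z)
    denom = float(z @ z)
    i_obs = n / s0 * float(z @ (W_dense @ z)) / denom
    perms = rng.permuted(np.tile(z, (B, 1)), axis=1)  # B x n
    wq = perms @ W_dense  # B x n
    i_perm = n / s0 * np.einsum("ij,ij->i", perms, wq) / denom
    p = (1.0 + float(np.sum(i_perm >= i_obs))) / (B + 1.0)
    return i_obs, p


def detect_regional_patterns(
    q: QuantMatrix,
    g: SpatialGrid,
    B: int = 999,
    seed: int = 0,
    min_obs: int = MIN_OBS_PATTERN,
) -> list[PatternResult]:
    """Flag proteins with spatially non-random (regional) distributions.

    For every protein, Moran's I under rook adjacency on its observed wells
    is compared with a null built by permuting the values across those same
    wells (B permutations); p-values are BH-adjusted across proteins.
    Proteins with fewer than ``min_obs`` observed wells, or constant values,
    are skipped with a warning.
    """
    if B < 99:
        raise ValueError("need at least 99 permutations for a usable p-value")
    qg = match_samples(q, g)
    vals = qg.values.to_numpy()
    cols = list(qg.values.columns)
    W_full = rook_adjacency(g)
    W_full_dense = W_full.toarray()
    s0_full = float(W_full.sum())
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(cols))

    results: list[PatternResult] = []
    skipped = []
    for j, pid in enumerate(cols):
        x = vals[:, j]
        mask = ~np.isnan(x)
        n = int(mask.sum())
        if n < min_obs:
            skipped.append(pid)
            continue
        xo = x[mask]
        if np.ptp(xo) == 0:
            skipped.append(pid)
            continue
        rng = np.random.default_rng(child_seeds[j])
        if n == len(x):  # fully observed: reuse the full-grid adjacency
            Wd, s0 = W_full_dense, s0_full
        else:
            W_sub = W_full[mask][:, mask]
            s0 = float(W_sub.sum())
            if s0 == 0:
                skipped.append(pid)
                continue
            Wd = W_sub.toarray()
        z = xo - xo.mean()
        i_obs, p = _moran_permutation_p(z, Wd, s0, B, rng)
        results.append(
            PatternResult(
                protein_id=pid,
                statistic=i_obs,
                p_perm=p,
                q_value=np.nan,
                n_permutations=B,
                seed=seed,
                n_observed=n,
            )
        )
    if skipped:
        logger.warning(
            "%d protein(s) skipped in pattern detection (<%d observed wells, "
            "constant, or isolated wells), e.g. %s",
            len(skipped),
            min_obs,
            skipped[:3],
        )
    if results:
        qvals = stats.false_discovery_control([r.p_perm for r in results], method="bh")
        for r, qv in zip(results, qvals):
            r.q_value = float(qv)
    return results
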