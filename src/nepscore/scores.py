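"""Neighbor-preference (NEP) scores: bi-directional counting, total vs
conditional normalization, the label-permutation null, and the score
family built on top of it.

Counting conventions
--------------------
For cell types i, j with cell sets C_i, C_j on a symmetric boolean
adjacency A:

* ``N[i, j]`` — ordered-pair edge count, sum over s in C_i, t in C_j of
  A_st.  On the diagonal each undirected homotypic edge contributes two
  ordered pairs, so ``N[i, i]`` is even.
* ``M[i, j]`` — number of type-i cells with at least one type-j
  neighbor (the conditional denominator).
* total normalization:        ``O_total[i, j] = N[i, j] / |C_i|``
* conditional normalization:  ``O_cond[i, j]  = N[i, j] / M[i, j]``
* conditional cell ratio:     ``CCR[i, j]     = M[i, j] / |C_i|``

The permutation null shuffles cell-type labels uniformly across all
cells of the image while the graph stays fixed.  One seeded permutation
sequence per image serves every ordered pair and every score, which
makes the total z-score exactly symmetric (``N`` is symmetric in every
draw and the constant denominators |C_i| cancel) while the conditional
z-score (COZI) is free to differ between directions.

Under permutation the conditional statistic recomputes *both* N and M:
the null is the null of O, and O depends on M.

Missing-value policy: a pair with observed M = 0 has no conditional
statistic (score is NaN, CCR = 0); a pair whose null is degenerate
(sigma_perm = 0) is NaN as well, never +/-inf.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_table import CellTable, SCORE_COLUMNS, sort_scores
from .errors import DegenerateGeometryError, ParameterError, ValidationError
from .graph import NeighborGraph, build_graph

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 300


# ---------------------------------------------------------------------------
# observed counts


@dataclass(frozen=True)
class PairCounts:
    """Ordered-pair edge counts N, conditional denominators M and the
    per-type cell counts of one image."""

    N: np.ndarray  # (K, K) int
    M: np.ndarray  # (K, K) int
    type_counts: np.ndarray  # (K,) int


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((len(labels), k))
    L[np.arange(len(labels)), labels] = 1.0
    return L


def count_pairs(graph: NeighborGraph, labels, k_types: int | None = None) -> PairCounts:
    """Count neighbor pairs bi-directionally on a symmetric graph.

    ``labels`` are integer type codes in ``[0, K)``; ``k_types`` fixes K
    (defaults to ``max(labels) + 1``).
    """
    labels = np.asarray(labels, dtype=np.intp)
    if len(labels) != graph.n_cells:
        raise ValidationError(
            f"labels length {len(labels)} != n_cells {graph.n_cells}"
        )
    k = int(k_types) if k_types is not None else int(labels.max()) + 1 if len(labels) else 0
    L = _one_hot(labels, k)
    A = graph.adjacency()
    T = A @ L  # T[s, j] = number of type-j neighbors of cell s
    N = (L.T @ T).astype(np.int64)
    M = (L.T @ (T > 0)).astype(np.int64)
    return PairCounts(N=N, M=M, type_counts=np.bincount(labels, minlength=k))


def normalize_total(counts: PairCounts) -> np.ndarray:
    """N[i, j] / |C_i|; rows of absent types are NaN."""
    denom = counts.type_counts.astype(float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = counts.N / denom
    out[counts.type_counts == 0, :] = np.nan
    return out


def normalize_conditional(counts: PairCounts) -> np.ndarray:
    """N[i, j] / M[i, j]; NaN where M = 0 (no interacting index cells)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(counts.M > 0, counts.N / np.maximum(counts.M, 1), np.nan)
    return out


def conditional_cell_ratio(counts: PairCounts) -> np.ndarray:
    """CCR[i, j] = M[i, j] / |C_i|, the fraction of type-i cells touching
    at least one type-j cell; NaN rows for absent types."""
    denom = counts.type_counts.astype(float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = counts.M / denom
    out[counts.type_counts == 0, :] = np.nan
    return out


# ---------------------------------------------------------------------------
# permutation engine


@dataclass(frozen=True)
class PermutationCounts:
    """Per-permutation N and M matrices from one shared label-shuffle
    stream; the raw material for every permutation-based score."""

    N: np.ndarray  # (n_perm, K, K)
    M: np.ndarray  # (n_perm, K, K)
    type_counts: np.ndarray  # (K,) — invariant under label permutation
    n_perm: int
    seed: int


@dataclass(frozen=True)
class PermutationNull:
    """Null moments of one normalized statistic, plus its per-permutation
    draws (needed for empirical tail counts)."""

    mu: np.ndarray  # (K, K)
    sigma: np.ndarray  # (K, K), ddof=0 over valid draws
    stats: np.ndarray  # (n_perm, K, K) with NaN where undefined
    n_valid: np.ndarray  # (K, K) number of non-NaN draws
    n_perm: int
    seed: int


def permute_counts(
    graph: NeighborGraph, labels, k_types: int, n_perm: int, seed: int
) -> PermutationCounts:
    """Run the shared permutation stream once for an image.

    Labels are shuffled uniformly over all cells; the identical sequence
    of permutations serves every ordered pair and every score derived
    from the returned counts.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    labels = np.asarray(labels, dtype=np.intp)
    rng = np.random.default_rng(seed)
    A = graph.adjacency()
    k = int(k_types)
    N = np.empty((n_perm, k, k))
    M = np.empty((n_perm, k, k))
    for p in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        L = _one_hot(perm, k)
        T = A @ L
        N[p] = L.T @ T
        M[p] = L.T @ (T > 0)
    return PermutationCounts(
        N=N, M=M, type_counts=np.bincount(labels, minlength=k),
        n_perm=int(n_perm), seed=int(seed),
    )


def _null_stats(pc: PermutationCounts, normalizer: str) -> np.ndarray:
    """Per-permutation normalized statistics, (n_perm, K, K)."""
    if normalizer == "total":
        denom = pc.type_counts.astype(float)[None, :, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            stats = pc.N / denom
        stats[:, pc.type_counts == 0, :] = np.nan
        return stats
    if normalizer == "conditional":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(pc.M > 0, pc.N / np.maximum(pc.M, 1), np.nan)
    if normalizer == "none":  # non-directional raw counts (CPscore)
        return _nondirectional(pc.N)
    raise ParameterError(f"unknown normalizer {normalizer!r}")


def _nondirectional(N: np.ndarray) -> np.ndarray:
    """Undirected pair counts: off-diagonal N (already one count per
    undirected edge), diagonal halved (homotypic edges double-counted)."""
    out = N.astype(float).copy()
    diag = np.arange(N.shape[-1])
    out[..., diag, diag] = out[..., diag, diag] / 2.0
    return out


def null_from_counts(pc: PermutationCounts, normalizer: str) -> PermutationNull:
    stats = _null_stats(pc, normalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mu = np.nanmean(stats, axis=0)
        sigma = np.nanstd(stats, axis=0, ddof=0)
    n_valid = np.sum(~np.isnan(stats), axis=0)
    return PermutationNull(
        mu=mu, sigma=sigma, stats=stats, n_valid=n_valid,
        n_perm=pc.n_perm, seed=pc.seed,
    )


def permutation_null(
    graph: NeighborGraph,
    labels,
    normalizer: str = "conditional",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    k_types: int | None = None,
) -> PermutationNull:
    """Convenience wrapper: shuffle labels and return the null of one
    normalized statistic (``total``, ``conditional`` or ``none`` for the
    non-directional raw count)."""
    labels = np.asarray(labels, dtype=np.intp)
    k = int(k_types) if k_types is not None else int(labels.max()) + 1
    pc = permute_counts(graph, labels, k, n_perm, seed)
    return null_from_counts(pc, normalizer)


def _zscore(observed: np.ndarray, null: PermutationNull) -> np.ndarray:
    """(obs - mu)/sigma with NaN where the observed statistic or the null
    is undefined or degenerate (sigma = 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null.mu) / null.sigma
    z[~np.isfinite(z)] = np.nan
    return z


# ---------------------------------------------------------------------------
# the score family


@dataclass(frozen=True)
class ScoreResult:
    """One K×K score matrix plus companions for one image."""

    score: np.ndarray  # (K, K) float, NaN = missing
    ccr: np.ndarray | None  # (K, K) or None for scores without CCR
    name: str
    n_perm: int
    seed: int
    degenerate_null: np.ndarray = field(default=None)  # type: ignore[assignment]
    # degenerate_null[i, j] True where sigma_perm = 0 forced a missing score


def cozi(
    graph: NeighborGraph,
    labels,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    size_correction: bool = False,
    k_types: int | None = None,
    _pc: PermutationCounts | None = None,
) -> ScoreResult:
    """Conditional z-score (COZI) with the conditional cell ratio.

    ``COZI[i, j] = (O_cond[i, j] - mu_perm) / sigma_perm`` where the null
    recomputes both the numerator N and the denominator M per
    permutation.  With ``size_correction`` every score is divided by
    sqrt(number of cells in the image), which removes the cell-count
    effect on z-score magnitudes.
    """
    labels = np.asarray(labels, dtype=np.intp)
    k = int(k_types) if k_types is not None else int(labels.max()) + 1
    pc = _pc if _pc is not None else permute_counts(graph, labels, k, n_perm, seed)
    obs = count_pairs(graph, labels, k)
    null = null_from_counts(pc, "conditional")
    z = _zscore(normalize_conditional(obs), null)
    degenerate = (null.sigma == 0) & (obs.M > 0)
    if size_correction:
        z = z / np.sqrt(graph.n_cells)
    return ScoreResult(
        score=z, ccr=conditional_cell_ratio(obs), name="cozi_z",
        n_perm=pc.n_perm, seed=pc.seed, degenerate_null=degenerate,
    )


def total_zscore(
    graph: NeighborGraph,
    labels,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    size_correction: bool = False,
    k_types: int | None = None,
    _pc: PermutationCounts | None = None,
) -> ScoreResult:
    """Total-normalized permutation z-score (the SEA-style score).

    Exactly symmetric in (i, j) under the shared permutation stream.
    """
    labels = np.asarray(labels, dtype=np.intp)
    k = int(k_types) if k_types is not None else int(labels.max()) + 1
    pc = _pc if _pc is not None else permute_counts(graph, labels, k, n_perm, seed)
    obs = count_pairs(graph, labels, k)
    # z on the raw ordered-pair counts: the constant |C_i| denominators of
    # O_total cancel, which keeps Z bitwise symmetric (N is symmetric in
    # every permutation draw)
    mu = pc.N.mean(axis=0)
    sigma = pc.N.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs.N - mu) / sigma
    z[~np.isfinite(z)] = np.nan
    z[pc.type_counts == 0, :] = np.nan
    z[:, pc.type_counts == 0] = np.nan
    if size_correction:
        z = z / np.sqrt(graph.n_cells)
    return ScoreResult(
        score=z, ccr=conditional_cell_ratio(obs), name="total_z",
        n_perm=pc.n_perm, seed=pc.seed, degenerate_null=(sigma == 0),
    )


def sigval(
    graph: NeighborGraph,
    labels,
    averaging: str = "histocat-conditional",
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.01,
    seed: int = 0,
    k_types: int | None = None,
    _pc: PermutationCounts | None = None,
) -> ScoreResult:
    """Categorical two-tailed permutation outcome in {-1, 0, +1}.

    ``averaging`` selects the normalization: ``"classic-total"`` divides
    by |C_i| (IMCRtools classic), ``"histocat-conditional"`` divides by M
    (histoCAT).  Empirical one-sided p-values use the add-one estimator
    ``p = (1 + #{perm >= obs}) / (n_valid + 1)``; +1 if the upper tail is
    significant at ``alpha``, -1 if the lower tail is, else 0.  Pairs
    with a missing observed statistic report 0.

    ``alpha`` must lie in (0, 1); values >= 0.5 are accepted but make the
    two-tailed reading meaningless (both tails can fire).
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    norm = {"classic-total": "total", "histocat-conditional": "conditional"}.get(averaging)
    if norm is None:
        raise ParameterError(f"unknown averaging {averaging!r}")
    labels = np.asarray(labels, dtype=np.intp)
    k = int(k_types) if k_types is not None else int(labels.max()) + 1
    pc = _pc if _pc is not None else permute_counts(graph, labels, k, n_perm, seed)
    obs_counts = count_pairs(graph, labels, k)
    observed = normalize_total(obs_counts) if norm == "total" else normalize_conditional(obs_counts)
    null = null_from_counts(pc, norm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ge = np.nansum(null.stats >= observed[None], axis=0)
        le = np.nansum(null.stats <= observed[None], axis=0)
    p_hi = (1.0 + ge) / (null.n_valid + 1.0)
    p_lo = (1.0 + le) / (null.n_valid + 1.0)
    sig = np.zeros((k, k))
    sig[(p_hi <= alpha) & (p_hi <= p_lo)] = 1.0
    sig[(p_lo <= alpha) & (p_lo < p_hi)] = -1.0
    sig[np.isnan(observed)] = 0.0
    name = "sigval_classic" if norm == "total" else "sigval_histocat"
    return ScoreResult(
        score=sig, ccr=conditional_cell_ratio(obs_counts), name=name,
        n_perm=pc.n_perm, seed=pc.seed, degenerate_null=(null.sigma == 0),
    )


def cpscore(
    graph: NeighborGraph,
    labels,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    k_types: int | None = None,
    _pc: PermutationCounts | None = None,
) -> ScoreResult:
    """Cell proximity score (Giotto-style): the non-directional observed
    pair count divided by its permutation-null mean; NaN if that mean is
    zero.  Returned as a symmetric K×K matrix; serialization stores the
    upper triangle once."""
    labels = np.asarray(labels, dtype=np.intp)
    k = int(k_types) if k_types is not None else int(labels.max()) + 1
    pc = _pc if _pc is not None else permute_counts(graph, labels, k, n_perm, seed)
    obs = _nondirectional(count_pairs(graph, labels, k).N.astype(float))
    null_mean = _nondirectional(pc.N).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = obs / null_mean
    score[~np.isfinite(score)] = np.nan
    return ScoreResult(
        score=score, ccr=None, name="cpscore",
        n_perm=pc.n_perm, seed=pc.seed, degenerate_null=(null_mean == 0),
    )


# ---------------------------------------------------------------------------
# per-image orchestration


def derive_seed(master_seed: int, image_id: str) -> int:
    """Stable, order-independent per-image seed below 2^31."""
    digest = hashlib.sha256(f"{int(master_seed)}:{image_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_SCORE_DISPATCH = {
    "cozi_z": lambda g, l, k, pc, n_perm, seed, size_corr, alpha: cozi(
        g, l, n_perm, seed, size_corr, k, _pc=pc
    ),
    "total_z": lambda g, l, k, pc, n_perm, seed, size_corr, alpha: total_zscore(
        g, l, n_perm, seed, size_corr, k, _pc=pc
    ),
    "sigval_classic": lambda g, l, k, pc, n_perm, seed, size_corr, alpha: sigval(
        g, l, "classic-total", n_perm, alpha, seed, k, _pc=pc
    ),
    "sigval_histocat": lambda g, l, k, pc, n_perm, seed, size_corr, alpha: sigval(
        g, l, "histocat-conditional", n_perm, alpha, seed, k, _pc=pc
    ),
    "cpscore": lambda g, l, k, pc, n_perm, seed, size_corr, alpha: cpscore(
        g, l, n_perm, seed, k, _pc=pc
    ),
}


def score_images(
    cells: CellTable,
    graph_method: str = "delaunay",
    k: int | None = None,
    r: float | None = None,
    scores: tuple[str, ...] = ("cozi_z",),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    size_correction: bool = False,
    alpha: float = 0.01,
    exclude_label: str | None = "exclude",
) -> pd.DataFrame:
    """Score every image of a cell table; returns the long-format table.

    One graph and one permutation stream are built per image; all
    requested scores share that stream.  Per-image seeds derive
    deterministically from ``seed`` and the image id.  Images failing the
    graph preconditions are skipped with a warning.
    """
    unknown = set(scores) - set(_SCORE_DISPATCH)
    if unknown:
        raise ParameterError(f"unknown score(s): {sorted(unknown)}")
    if graph_method == "knn" and not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ParameterError(f"knn graph requires a positive integer k, got {k!r}")
    if graph_method == "radius" and not (r is not None and r > 0):
        raise ParameterError(f"radius graph requires r > 0, got {r!r}")
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    if exclude_label is not None and exclude_label in cells.label_set:
        cells = cells.drop_label(exclude_label)
    types = cells.label_set
    kt = len(types)
    rows = []
    for image_id in cells.image_ids():
        img = cells.image(image_id)
        try:
            graph = build_graph(img, graph_method, k=k, r=r)
        except (DegenerateGeometryError, ParameterError) as exc:
            # per-image precondition failures (too few cells for the
            # triangulation, k >= n_cells): skip, keep the run going
            logger.warning("SKIP_IMAGE image=%s reason=%s", image_id, exc)
            continue
        labels = img.labels()
        img_seed = derive_seed(seed, image_id)
        pc = permute_counts(graph, labels, kt, n_perm, img_seed)
        for score_name in scores:
            res = _SCORE_DISPATCH[score_name](
                graph, labels, kt, pc, n_perm, img_seed, size_correction, alpha
            )
            for i, ti in enumerate(types):
                for j, tj in enumerate(types):
                    if score_name == "cpscore" and i > j:
                        continue  # non-directional: store upper triangle once
                    rows.append(
                        (
                            image_id, ti, tj, score_name,
                            float(res.score[i, j]),
                            float(res.ccr[i, j]) if res.ccr is not None else np.nan,
                            n_perm, img_seed, graph.n_cells,
                        )
                    )
    out = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    return sort_scores(out)
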