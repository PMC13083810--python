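"""Ground-truth-labeled synthetic tissues.

Two generators are provided:

* an *in silico tissue* (IST) style pipeline — a random-circle-packing
  scaffold converted to a Voronoi/Delaunay graph whose nodes are labeled
  by a heuristic that targets an abundance vector ``p`` and a
  row-stochastic directed adjacency-probability matrix ``H`` (H[i, j] is
  the probability that a neighbor of a type-i cell is type j);
* a hard-core point-pattern generator with elliptical clusters and
  progressive cluster infiltration.

The IST heuristic prioritizes adherence to the adjacency matrix over
exact abundances, so realized abundances can drift from ``p`` — this is
a property of the heuristic, most visible for rare types asked to keep
strong preferences.

The preset ``p`` vectors and ``H`` matrices used throughout the tests
(ABUNDANCE_VECTORS, self_preference_matrix, cross_preference_matrix)
define two cohort families: symmetric self-preference of type 0 and
asymmetric cross-preference of type 0 for type 1, each at three levels
(random 0.25, weak 0.45, strong 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cell_table import CellTable
from .errors import PackingError, ParameterError, ValidationError
from .graph import NeighborGraph, build_delaunay
from .scores import count_pairs, derive_seed
import pandas as pd

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class AdjacencySpec:
    """Ground truth of a simulated cohort: abundances p and directed
    adjacency probabilities H (row-stochastic, K×K)."""

    p: np.ndarray
    H: np.ndarray
    cohort_label: str = ""
    type_names: tuple[str, ...] | None = None

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        H = np.asarray(self.H, dtype=float)
        if p.ndim != 1 or H.shape != (len(p), len(p)):
            raise ValidationError("p must be length-K and H K×K")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValidationError("p must be nonnegative and sum to 1")
        if (H < 0).any() or np.abs(H.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValidationError("every row of H must be nonnegative and sum to 1")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "H", H)
        names = self.type_names or tuple(f"type{i}" for i in range(len(p)))
        if len(names) != len(p):
            raise ValidationError("type_names length must equal K")
        object.__setattr__(self, "type_names", tuple(names))

    @property
    def k_types(self) -> int:
        return len(self.p)


# preset 4-type cohort tables: type 0 varies in abundance, types 1-3 share
# the remainder; adjacency levels random / weak / strong
ABUNDANCE_VECTORS = {
    "ab0_0.05": (0.05, 0.32, 0.32, 0.31),
    "ab0_0.1": (0.10, 0.30, 0.30, 0.30),
    "ab0_0.15": (0.15, 0.28, 0.28, 0.29),
    "ab0_0.2": (0.20, 0.27, 0.27, 0.26),
    "ab0_0.25": (0.25, 0.25, 0.25, 0.25),
    "ab0_0.35": (0.35, 0.22, 0.22, 0.21),
    "ab0_0.45": (0.45, 0.18, 0.18, 0.19),
    "ab0_0.55": (0.55, 0.15, 0.15, 0.15),
}

_SELF_H = {
    "random": [
        (0.25, 0.25, 0.25, 0.25),
        (0.25, 0.25, 0.25, 0.25),
        (0.25, 0.25, 0.25, 0.25),
        (0.25, 0.25, 0.25, 0.25),
    ],
    "weak": [
        (0.45, 0.18, 0.18, 0.19),
        (0.18, 0.27, 0.28, 0.27),
        (0.18, 0.28, 0.27, 0.27),
        (0.19, 0.27, 0.27, 0.27),
    ],
    "strong": [
        (0.60, 0.13, 0.13, 0.14),
        (0.13, 0.29, 0.29, 0.29),
        (0.13, 0.29, 0.29, 0.29),
        (0.14, 0.29, 0.29, 0.28),
    ],
}

_CROSS_H = {
    "random": _SELF_H["random"],
    "weak": [
        (0.18, 0.45, 0.18, 0.19),
        (0.27, 0.18, 0.28, 0.27),
        (0.28, 0.18, 0.27, 0.27),
        (0.27, 0.19, 0.27, 0.27),
    ],
    "strong": [
        (0.13, 0.60, 0.13, 0.14),
        (0.29, 0.13, 0.29, 0.29),
        (0.29, 0.13, 0.29, 0.29),
        (0.29, 0.14, 0.29, 0.28),
    ],
}


def self_preference_matrix(level: str) -> np.ndarray:
    """Self-preference H for type 0 at level random/weak/strong
    (H[0,0] = 0.25 / 0.45 / 0.60)."""
    return np.array(_SELF_H[level], dtype=float)


def cross_preference_matrix(level: str) -> np.ndarray:
    """Cross-preference H of type 0 for type 1 at level random/weak/strong
    (H[0,1] = 0.25 / 0.45 / 0.60; note H[1,0] stays near 0.27-0.29, which
    makes the matrix directional)."""
    return np.array(_CROSS_H[level], dtype=float)


def preset_spec(kind: str, level: str, abundance: str = "ab0_0.25") -> AdjacencySpec:
    """Build an AdjacencySpec from the preset tables.

    ``kind`` is ``"self"`` or ``"cross"``; ``level`` is random/weak/strong;
    ``abundance`` keys into ABUNDANCE_VECTORS.
    """
    H = self_preference_matrix(level) if kind == "self" else cross_preference_matrix(level)
    return AdjacencySpec(
        p=np.array(ABUNDANCE_VECTORS[abundance]),
        H=H,
        cohort_label=f"{kind}_{level}_{abundance}",
    )


# ---------------------------------------------------------------------------
# IST scaffold: circle packing + Voronoi graph


@dataclass(frozen=True)
class SimParams:
    """IST generator parameters: field size f, cell radii, annotation grid
    size t, graph distance for label borrowing, refinement iterations I
    and swaps-per-iteration S."""

    f: float = 1000.0
    r_min: float = 10.0
    r_max: float = 10.0
    t: float = 200.0
    graph_distance: int = 2
    iterations: int = 300
    swaps: int = 50
    retry_budget: int = 10_000


def pack_circles(
    f: float, r_min: float, r_max: float, seed: int, retry_budget: int = 10_000
):
    """Random circle packing by rejection sampling.

    Radii are drawn uniformly from [r_min, r_max]; a candidate center is
    accepted when its circle overlaps no accepted circle and lies fully
    inside [0, f]².  Packing stops when ``retry_budget`` consecutive
    rejections accumulate, i.e. near saturation.

    Returns (centers (n, 2), radii (n,)).
    """
    if not (0 < r_min <= r_max):
        raise ParameterError("need 0 < r_min <= r_max")
    if r_max > f / 2:
        raise ParameterError(f"r_max={r_max} too large for field f={f}")
    rng = np.random.default_rng(seed)
    cell = 2.0 * r_max  # grid bucket size: overlaps confined to 3x3 buckets
    grid: dict[tuple[int, int], list[int]] = {}
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    failures = 0
    while failures < retry_budget:
        r = r_min if r_min == r_max else rng.uniform(r_min, r_max)
        x = rng.uniform(r, f - r)
        y = rng.uniform(r, f - r)
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for idx in grid.get((ix, iy), ()):
                    cx, cy = centers[idx]
                    dx, dy = x - cx, y - cy
                    lim = r + radii[idx]
                    if dx * dx + dy * dy < lim * lim:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(centers))
            centers.append((x, y))
            radii.append(r)
            failures = 0
        else:
            failures += 1
    return np.array(centers), np.array(radii)


def scaffold_graph(points: np.ndarray) -> NeighborGraph:
    """Voronoi adjacency of scaffold centers: pairs whose Voronoi cells
    share a boundary, i.e. the Delaunay edges of the centers."""
    return build_delaunay(points)


@dataclass
class Scaffold:
    """A blank tissue scaffold: packed centers, its Voronoi graph, and the
    precomputed within-distance-d neighbor lists used by annotation."""

    points: np.ndarray
    graph: NeighborGraph
    nbrs1: list[np.ndarray]
    nbrs_within: list[np.ndarray]  # within graph_distance hops, self excluded
    f: float
    seed: int


def _hop_neighbors(nbrs1: list[np.ndarray], distance: int) -> list[np.ndarray]:
    out = []
    for v, first in enumerate(nbrs1):
        seen = {v}
        frontier = [int(u) for u in first]
        seen.update(frontier)
        acc = list(frontier)
        for _ in range(distance - 1):
            nxt = []
            for u in frontier:
                for w in nbrs1[u]:
                    w = int(w)
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            acc.extend(nxt)
            frontier = nxt
        out.append(np.array(sorted(acc), dtype=np.intp))
    return out


def make_scaffold(params: SimParams, seed: int) -> Scaffold:
    points, _ = pack_circles(
        params.f, params.r_min, params.r_max, seed, params.retry_budget
    )
    graph = scaffold_graph(points)
    nbrs1 = graph.neighbor_lists()
    return Scaffold(
        points=points,
        graph=graph,
        nbrs1=nbrs1,
        nbrs_within=_hop_neighbors(nbrs1, params.graph_distance),
        f=params.f,
        seed=seed,
    )


def make_scaffolds(n: int, params: SimParams, seed: int) -> list[Scaffold]:
    """Independent scaffolds for a cohort; reuse the same list across
    cohorts to share scaffolds."""
    return [make_scaffold(params, derive_seed(seed, f"scaffold_{i}")) for i in range(n)]


# ---------------------------------------------------------------------------
# heuristic annotation


@dataclass
class SimulatedTissue:
    cells: CellTable
    scaffold: NeighborGraph
    truth: AdjacencySpec
    sim_params: SimParams
    seed: int
    image_id: str


def _region_of(points, origin, t):
    return np.floor((points - origin) / t).astype(int)


def annotate_heuristic(
    scaffold: Scaffold,
    spec: AdjacencySpec,
    params: SimParams,
    seed: int,
    image_id: str = "image0",
) -> SimulatedTissue:
    """Label scaffold nodes toward (p, H) with the grid-growth heuristic.

    1. Partition the field into t×t regions (row-major traversal).
    2. Seed one random region: its nodes draw labels iid from p.
    3. Grow: every unlabeled node whose graph-distance-``d`` neighborhood
       contains a labeled node samples its label from the H row of the
       nearest labeled neighbor (nearest by hop count, ties by index);
       the grid is then shifted by t/2 in x and y and the pass repeats,
       alternating, until all nodes are labeled.
    4. Refine: for ``iterations`` rounds, pick ``swaps`` random nodes;
       for each, compare its neighborhood label composition with the H
       row of its own label, locate a nearby node of the most
       over-represented type, and exchange its label with that of a
       random node of the most under-represented type.  An exchange is
       kept only if it moves the image's realized adjacency fractions
       closer to H (squared-error hill climb), so refinement conserves
       abundances exactly and adherence to H takes priority over the
       initial spatial arrangement.
    """
    rng = np.random.default_rng(seed)
    pts = scaffold.points
    n = len(pts)
    k = spec.k_types
    t = params.t
    labels = np.full(n, -1, dtype=np.intp)

    # (2) initial region seeded from Multinomial(p)
    reg = _region_of(pts, np.zeros(2), t)
    region_keys = sorted({(int(a), int(b)) for a, b in reg})
    start = region_keys[rng.integers(len(region_keys))]
    in_start = (reg[:, 0] == start[0]) & (reg[:, 1] == start[1])
    labels[in_start] = rng.choice(k, size=int(in_start.sum()), p=spec.p)

    # (3) growth passes over alternating grid offsets
    offsets = [np.zeros(2), np.array([t / 2.0, t / 2.0])]
    max_passes = 200
    for pass_no in range(max_passes):
        if (labels >= 0).all():
            break
        origin = offsets[pass_no % 2]
        reg = _region_of(pts, origin, t)
        order = np.lexsort((np.arange(n), reg[:, 0], reg[:, 1]))  # row-major regions
        for v in order:
            if labels[v] >= 0:
                continue
            src = -1
            for u in scaffold.nbrs1[v]:  # hop 1 first, lowest index
                if labels[u] >= 0:
                    src = int(u)
                    break
            if src < 0:
                for u in scaffold.nbrs_within[v]:
                    if labels[u] >= 0:
                        src = int(u)
                        break
            if src >= 0:
                labels[v] = rng.choice(k, p=spec.H[labels[src]])
    if (labels < 0).any():
        raise RuntimeError("annotation left unlabeled nodes; scaffold disconnected?")

    # (4) refinement toward H: abundance-conserving label exchanges,
    # accepted only when the realized adjacency fractions move closer to H
    _refine_labels(labels, scaffold, spec, params, rng)

    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "cell_type": [spec.type_names[i] for i in labels],
            "image_id": image_id,
        }
    )
    cells = CellTable(df, label_set=spec.type_names)
    return SimulatedTissue(
        cells=cells, scaffold=scaffold.graph, truth=spec,
        sim_params=params, seed=seed, image_id=image_id,
    )


def _adjacency_loss(N: np.ndarray, H: np.ndarray) -> float:
    """Squared error between row-normalized ordered-pair counts and H."""
    row = N.sum(axis=1, keepdims=True)
    F = np.where(row > 0, N / np.maximum(row, 1.0), 0.0)
    return float(((F - H) ** 2).sum())


def _relabel(N: np.ndarray, labels: np.ndarray, nbrs1, node: int, new: int) -> None:
    """Relabel one node, updating ordered-pair counts N in place."""
    old = labels[node]
    for t in nbrs1[node]:
        c = labels[t]
        N[old, c] -= 1
        N[c, old] -= 1
        N[new, c] += 1
        N[c, new] += 1
    labels[node] = new


def _refine_labels(labels, scaffold: Scaffold, spec: AdjacencySpec,
                   params: SimParams, rng) -> None:
    k = spec.k_types
    if k < 2 or params.iterations < 1:
        return
    n = len(labels)
    N = count_pairs(scaffold.graph, labels, k).N.astype(float)
    loss = _adjacency_loss(N, spec.H)
    for _ in range(params.iterations):
        for v in rng.choice(n, size=min(params.swaps, n), replace=False):
            nb = scaffold.nbrs_within[v]
            if len(nb) == 0:
                continue
            comp = np.bincount(labels[nb], minlength=k) / len(nb)
            delta = comp - spec.H[labels[v]]
            over = int(np.argmax(delta))
            under = int(np.argmin(delta))
            if over == under or delta[over] <= 0 or delta[under] >= 0:
                continue
            cand = [int(u) for u in scaffold.nbrs1[v] if labels[u] == over]
            if not cand:
                cand = [int(u) for u in nb if labels[u] == over]
            if not cand:
                continue
            u = cand[0]
            # move 1: plain relabel of u (lets abundances drift toward
            # what H demands — adjacency adherence has priority)
            _relabel(N, labels, scaffold.nbrs1, u, under)
            relabel_loss = _adjacency_loss(N, spec.H)
            # move 2: abundance-conserving exchange with a random node of
            # the under-represented type
            pool = np.flatnonzero(labels == under)
            pool = pool[pool != u]
            w = int(pool[rng.integers(len(pool))]) if len(pool) else -1
            if w >= 0:
                _relabel(N, labels, scaffold.nbrs1, w, over)
                exchange_loss = _adjacency_loss(N, spec.H)
            else:
                exchange_loss = np.inf
            if exchange_loss < min(loss, relabel_loss):
                loss = exchange_loss
            elif relabel_loss < loss:
                if w >= 0:
                    _relabel(N, labels, scaffold.nbrs1, w, under)
                loss = relabel_loss
            else:  # revert both
                if w >= 0:
                    _relabel(N, labels, scaffold.nbrs1, w, under)
                _relabel(N, labels, scaffold.nbrs1, u, over)


def simulate_cohort(
    spec: AdjacencySpec,
    n_images: int,
    params: SimParams | None = None,
    seed: int = 0,
    scaffolds: list[Scaffold] | None = None,
) -> list[SimulatedTissue]:
    """Generate a cohort of annotated tissues.

    Pass the same ``scaffolds`` list to several calls to share tissue
    scaffolds across cohorts (identical coordinates, cohort-specific
    labels); otherwise scaffolds are generated from ``seed``.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    params = params or SimParams()
    if scaffolds is None:
        scaffolds = make_scaffolds(n_images, params, seed)
    if len(scaffolds) < n_images:
        raise ParameterError("not enough scaffolds for n_images")
    tissues = []
    label = spec.cohort_label or "cohort"
    for i in range(n_images):
        image_id = f"{label}_{i:03d}"
        tissues.append(
            annotate_heuristic(
                scaffolds[i], spec, params,
                seed=derive_seed(seed, f"annotate_{label}_{i}"),
                image_id=image_id,
            )
        )
    return tissues


def cohort_to_table(tissues: list[SimulatedTissue]) -> CellTable:
    """Concatenate a cohort into one multi-image CellTable."""
    df = pd.concat([t.cells.df for t in tissues], ignore_index=True)
    return CellTable(df, label_set=tissues[0].cells.label_set)


def adjacency_fractions(graph: NeighborGraph, labels, k_types: int) -> np.ndarray:
    """Realized directed adjacency fractions: row i gives the label
    composition of the neighbors of type-i cells (the empirical analogue
    of a row of H).  NaN rows for types with no incident edges."""
    N = count_pairs(graph, labels, k_types).N.astype(float)
    row = N.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(row > 0, N / row, np.nan)


# ---------------------------------------------------------------------------
# hard-core point patterns with infiltrated clusters


@dataclass(frozen=True)
class ClusterSpec:
    """One elliptical cluster: cells inside the axis-aligned ellipse are
    relabeled to ``cell_type`` (nearest-to-center first, up to ``size``),
    then a fraction ``infiltration`` of them is relabeled to
    ``infiltrating_type``."""

    cell_type: str
    size: int
    center: tuple[float, float]
    semi_axes: tuple[float, float] = (460.0, 320.0)
    infiltration: float = 0.0
    infiltrating_type: str | None = None


@dataclass(frozen=True)
class InfiltrationParams:
    """Hard-core background plus clusters (SpaSim-style scenario)."""

    width: float = 2000.0
    height: float = 2000.0
    n_background: int = 5000
    min_d: float = 10.0
    oversampling: float = 1.6
    background_type: str = "other"
    clusters: tuple[ClusterSpec, ...] = ()

    def __post_init__(self):
        if self.min_d <= 0:
            raise ParameterError("min_d must be positive")
        for c in self.clusters:
            if not (0.0 <= c.infiltration <= 1.0):
                raise ParameterError("infiltration proportion must be in [0, 1]")
            if c.infiltration > 0 and c.infiltrating_type is None:
                raise ParameterError("infiltration requires an infiltrating_type")


def _hardcore_points(params: InfiltrationParams, rng) -> np.ndarray:
    """Uniform candidates at oversampling × n, thinned greedily in draw
    order to enforce the minimum spacing, truncated to n."""
    n_cand = int(np.ceil(params.oversampling * params.n_background))
    cand = rng.uniform(
        [0.0, 0.0], [params.width, params.height], size=(n_cand, 2)
    )
    cell = params.min_d
    grid: dict[tuple[int, int], list[int]] = {}
    kept: list[int] = []
    min_d2 = params.min_d**2
    for i, (x, y) in enumerate(cand):
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for j in grid.get((ix, iy), ()):
                    dx, dy = x - cand[j, 0], y - cand[j, 1]
                    if dx * dx + dy * dy < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(i)
            kept.append(i)
            if len(kept) == params.n_background:
                return cand[kept]
    raise PackingError(
        f"placed only {len(kept)}/{params.n_background} points at min_d="
        f"{params.min_d}; reduce n_background or min_d, or raise oversampling"
    )


def simulate_infiltration(
    params: InfiltrationParams, seed: int, image_id: str = "image0"
) -> CellTable:
    """Hard-core background, elliptical clusters, progressive infiltration.

    Background cells carry ``params.background_type``; each cluster
    relabels up to ``size`` cells inside its ellipse; a fraction
    ``infiltration`` of each cluster's cells (uniform, without
    replacement) is then relabeled to the infiltrating type.
    """
    rng = np.random.default_rng(seed)
    pts = _hardcore_points(params, rng)
    types = np.array([params.background_type] * len(pts), dtype=object)
    label_set = {params.background_type}
    for cl in params.clusters:
        a, b = cl.semi_axes
        cx, cy = cl.center
        u = ((pts[:, 0] - cx) / a) ** 2 + ((pts[:, 1] - cy) / b) ** 2
        inside = np.flatnonzero((u <= 1.0) & (types == params.background_type))
        inside = inside[np.argsort(u[inside], kind="stable")]  # compact core first
        take = inside[: cl.size]
        types[take] = cl.cell_type
        label_set.add(cl.cell_type)
        if cl.infiltration > 0 and len(take):
            n_inf = int(round(cl.infiltration * len(take)))
            inf_idx = rng.choice(take, size=n_inf, replace=False)
            types[inf_idx] = cl.infiltrating_type
            label_set.add(cl.infiltrating_type)
        if cl.infiltrating_type:
            label_set.add(cl.infiltrating_type)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "cell_type": types,
            "image_id": image_id,
        }
    )
    return CellTable(df, label_set=tuple(sorted(label_set)))


#: green-cluster sizes paired with purple-cluster infiltration proportions
#: (0, 0.1, ..., 0.7) that keep total green ≈ total purple in scenario II
SCENARIO_II_GREEN_SIZES = (510, 500, 490, 480, 470, 460, 450, 440)
SCENARIO_PROPORTIONS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def infiltration_scenario(
    scenario: str, proportion: float, seed: int = 0, image_id: str | None = None
) -> CellTable:
    """The three preset infiltration scenarios.

    I   — one purple cluster of 500 cells, green cells infiltrating at
          ``proportion``.
    II  — purple cluster (500) infiltrated by green at ``proportion``,
          plus a green cluster sized to keep total green ≈ total purple.
    III — scenario II with purple and green labels switched.
    """
    scenario = scenario.upper()
    if proportion not in SCENARIO_PROPORTIONS:
        if not (0.0 <= proportion <= 1.0):
            raise ParameterError("proportion must be in [0, 1]")
    purple, green = "purple", "green"
    if scenario == "I":
        clusters = (
            ClusterSpec(purple, 500, (1000.0, 1000.0),
                        infiltration=proportion, infiltrating_type=green),
        )
    elif scenario in ("II", "III"):
        a, b = (purple, green) if scenario == "II" else (green, purple)
        if proportion in SCENARIO_PROPORTIONS:
            other_size = SCENARIO_II_GREEN_SIZES[SCENARIO_PROPORTIONS.index(proportion)]
        else:
            other_size = 510 - int(round(100 * proportion))
        clusters = (
            ClusterSpec(a, 500, (600.0, 600.0), semi_axes=(460.0, 320.0),
                        infiltration=proportion, infiltrating_type=b),
            ClusterSpec(b, other_size, (1450.0, 1450.0), semi_axes=(460.0, 320.0)),
        )
    else:
        raise ParameterError(f"unknown scenario {scenario!r}")
    params = InfiltrationParams(clusters=clusters)
    return simulate_infiltration(
        params, seed, image_id=image_id or f"scenario{scenario}_p{proportion}"
    )
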