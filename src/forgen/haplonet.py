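"""Haplotype collapsing, median-joining networks and isolation by distance.

Works on panels of fully homozygous accessions (inbred lines, landraces and
wild relatives of a selfing crop), where each accession's genotype at the
retained sites is a haplotype.  The pipeline is: filter sites to those nearly
always homozygous and drop accessions with heterozygous or missing calls at
the retained sites; collapse identical allele vectors into haplotypes; build
a mutation-weighted haplotype network (minimum spanning network or Bandelt
median-joining network); and test geographic structuring by regressing
pairwise Ritland kinship on geographic distance with a permutation test.

Genotype codes: ``0``/``1`` the two homozygous states, ``2`` heterozygous,
``-1`` missing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SnpMatrix",
    "HaplotypeSet",
    "filter_sites",
    "collapse_haplotypes",
    "build_network",
    "hamming",
    "geodesic_distance",
    "pairwise_geodesic",
    "ritland_kinship",
    "ibd_regression",
    "IbdResult",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class SnpMatrix:
    """Accessions x biallelic sites genotype matrix with optional metadata.

    ``metadata`` (if given) has one row per accession with at least an
    ``accession`` column; ``group``, ``lat``, ``lon`` are used downstream.
    """

    genotypes: np.ndarray
    accessions: list[str]
    sites: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != len(self.accessions):
            raise ValueError("genotype matrix shape does not match accession list")
        if not self.sites:
            self.sites = [f"site{j}" for j in range(self.genotypes.shape[1])]
        if len(self.sites) != self.genotypes.shape[1]:
            raise ValueError("site list does not match matrix width")
        if self.metadata is not None:
            self.metadata = self.metadata.set_index("accession").loc[self.accessions].reset_index()

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele 1 per site among homozygous calls."""
        g = self.genotypes
        hom = (g == 0) | (g == 1)
        with np.errstate(invalid="ignore"):
            return np.where(hom, g, 0).sum(axis=0) / hom.sum(axis=0)


def filter_sites(matrix: SnpMatrix, min_hom_fraction: float = 0.98) -> SnpMatrix:
    """Retain sites nearly always homozygous, then drop imperfect accessions.

    Sites with a homozygous-call fraction below ``min_hom_fraction`` (default
    0.98, i.e. >=98% of samples homozygous) are removed; accessions with any
    heterozygous or missing call at the retained sites are then excluded.
    Both removals are logged.
    """
    g = matrix.genotypes
    hom_frac = (((g == 0) | (g == 1)).sum(axis=0)) / matrix.n_accessions
    keep_sites = hom_frac >= min_hom_fraction
    n_dropped_sites = int((~keep_sites).sum())
    g2 = g[:, keep_sites]
    keep_acc = ((g2 == 0) | (g2 == 1)).all(axis=1)
    n_dropped_acc = int((~keep_acc).sum())
    logger.info(
        "filter_sites: removed %d/%d sites (<%.0f%% homozygous), excluded %d/%d accessions "
        "with het/missing calls at retained sites",
        n_dropped_sites, matrix.n_sites, 100 * min_hom_fraction, n_dropped_acc, matrix.n_accessions,
    )
    if keep_sites.sum() == 0:
        logger.warning("filter_sites: all sites removed — empty result")
    meta = None
    if matrix.metadata is not None:
        meta = matrix.metadata.loc[keep_acc].reset_index(drop=True)
    return SnpMatrix(
        genotypes=g2[keep_acc],
        accessions=[a for a, k in zip(matrix.accessions, keep_acc) if k],
        sites=[s for s, k in zip(matrix.sites, keep_sites) if k],
        metadata=meta,
    )


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with membership, ordered by descending count then
    first appearance."""

    vectors: np.ndarray  # n_haplotypes x n_sites, codes 0/1
    members: list[list[str]]
    counts: np.ndarray
    group_composition: list[dict[str, int]]

    @property
    def n_haplotypes(self) -> int:
        return len(self.vectors)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": [f"HP{i + 1}" for i in range(self.n_haplotypes)],
                "count": self.counts,
                "members": [",".join(m) for m in self.members],
                "groups": [
                    ";".join(f"{k}:{v}" for k, v in comp.items()) for comp in self.group_composition
                ],
            }
        )


def collapse_haplotypes(matrix: SnpMatrix) -> HaplotypeSet:
    """Group identical allele vectors into haplotypes.

    Requires a filtered matrix (homozygous calls only).  Haplotypes are
    ordered by descending member count, ties broken by first appearance.
    """
    g = matrix.genotypes
    if not np.isin(g, (0, 1)).all():
        raise ValueError("collapse_haplotypes requires a filtered, fully homozygous matrix")
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(g):
        groups.setdefault(row.tobytes(), []).append(i)
    order = sorted(groups.values(), key=lambda idx: (-len(idx), idx[0]))
    vectors = np.array([g[idx[0]] for idx in order], dtype=np.int8)
    members = [[matrix.accessions[i] for i in idx] for idx in order]
    counts = np.array([len(idx) for idx in order])
    comp = []
    if matrix.metadata is not None and "group" in matrix.metadata.columns:
        grp = matrix.metadata["group"].to_numpy()
        for idx in order:
            c: dict[str, int] = {}
            for i in idx:
                c[grp[i]] = c.get(grp[i], 0) + 1
            comp.append(c)
    else:
        comp = [{} for _ in order]
    return HaplotypeSet(vectors=vectors, members=members, counts=counts, group_composition=comp)


# ---------------------------------------------------------------------------
# Haplotype networks
# ---------------------------------------------------------------------------

def hamming(u: np.ndarray, v: np.ndarray) -> int:
    return int(np.count_nonzero(np.asarray(u) != np.asarray(v)))


def _distance_matrix(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors)
    return (v[:, None, :] != v[None, :, :]).sum(axis=2)


def _msn_edges(dist: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Minimum spanning network edges (union of all minimum spanning trees).

    Kruskal-style pass over distance classes: within each class, every edge
    joining components that were distinct at the start of the class is kept.
    ``epsilon`` relaxes each class to also admit edges up to ``epsilon``
    longer than the class weight.
    """
    n = len(dist)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = [(int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort()
    edges: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    k = 0
    while k < len(pairs):
        w = pairs[k][0]
        comp_before = [find(i) for i in range(n)]
        batch = [p for p in pairs if w <= p[0] <= w + epsilon]
        for wj, i, j in batch:
            if comp_before[i] != comp_before[j] and (i, j) not in seen:
                edges.append((i, j, wj))
                seen.add((i, j))
        for wj, i, j in batch:
            if wj == w:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        while k < len(pairs) and pairs[k][0] == w:
            k += 1
    return edges


def _mst_length(dist: np.ndarray) -> int:
    """Minimum spanning tree total length over a complete distance graph."""
    n = len(dist)
    if n <= 1:
        return 0
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].astype(float).copy()
    best[0] = np.inf
    total = 0
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        total += int(best[j])
        in_tree[j] = True
        best = np.minimum(best, dist[j])
    return total


def build_network(
    haplo_set: HaplotypeSet,
    method: str = "mjn",
    epsilon: int = 0,
    max_iter: int = 200,
) -> nx.Graph:
    """Build a mutation-weighted haplotype network.

    ``msn``: the minimum spanning network — the union of all minimum
    spanning trees over Hamming distances.

    ``mjn``: Bandelt-style median-joining.  Starting from the observed
    haplotypes, repeatedly propose the site-wise majority (median) vector of
    every node triple and add the median that most reduces the minimum
    spanning tree length of the node set; iterate to fixpoint, then prune
    inferred medians of network degree <= 2 (they lie on pairwise geodesics,
    so pruning never lengthens the network).

    Returns a :class:`networkx.Graph` whose nodes carry ``vector`` (tuple of
    0/1) and ``kind`` (``observed``/``median``) attributes, plus ``label``
    and ``count`` for observed haplotypes; edge attribute ``weight`` is the
    Hamming distance between endpoint vectors.
    """
    if haplo_set.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes to build a network")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if method not in ("mjn", "msn"):
        raise ValueError(f"unknown method {method!r}")

    observed = [tuple(int(x) for x in v) for v in haplo_set.vectors]
    nodes: list[tuple[int, ...]] = list(dict.fromkeys(observed))

    if method == "mjn":
        for _ in range(max_iter):
            vec = np.array(nodes, dtype=np.int8)
            dist = _distance_matrix(vec)
            base_len = _mst_length(dist)
            node_set = set(nodes)
            best_gain, best_median = 0, None
            seen: set[tuple[int, ...]] = set()
            for a, b, c in itertools.combinations(range(len(nodes)), 3):
                triple = vec[[a, b, c]]
                med = tuple(int(x) for x in (triple.sum(axis=0) >= 2).astype(int))
                if med in node_set or med in seen:
                    continue
                seen.add(med)
                mvec = np.array(med, dtype=np.int8)
                d_new = (vec != mvec).sum(axis=1)
                grown = np.pad(dist, ((0, 1), (0, 1)))
                grown[-1, :-1] = d_new
                grown[:-1, -1] = d_new
                gain = base_len - _mst_length(grown)
                if gain > best_gain or (gain == best_gain and gain > 0 and med < best_median):
                    best_gain, best_median = gain, med
            if best_median is None or best_gain <= 0:
                break
            nodes.append(best_median)
        # prune inferred medians until all have degree >= 3 in the network
        while True:
            edges = _msn_edges(_distance_matrix(np.array(nodes, dtype=np.int8)), epsilon)
            degree = {i: 0 for i in range(len(nodes))}
            for i, j, _w in edges:
                degree[i] += 1
                degree[j] += 1
            removable = [
                i for i in range(len(nodes)) if nodes[i] not in observed and degree[i] <= 2
            ]
            if not removable:
                break
            del nodes[removable[0]]

    edges = _msn_edges(_distance_matrix(np.array(nodes, dtype=np.int8)), epsilon)
    graph = nx.Graph(method=method, epsilon=epsilon)
    obs_index = {v: i for i, v in enumerate(observed)}
    for i, v in enumerate(nodes):
        if v in obs_index:
            k = obs_index[v]
            graph.add_node(
                i, vector=v, kind="observed", label=f"HP{k + 1}", count=int(haplo_set.counts[k])
            )
        else:
            graph.add_node(i, vector=v, kind="median", label=f"mv{i}", count=0)
    for i, j, w in edges:
        graph.add_edge(i, j, weight=int(w))
    return graph


# ---------------------------------------------------------------------------
# Geography and kinship
# ---------------------------------------------------------------------------

def geodesic_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle (haversine) distance in km, Earth radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def pairwise_geodesic(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances (km) between coordinates."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dp = lat[:, None] - lat[None, :]
    dl = lon[:, None] - lon[None, :]
    a = np.sin(dp / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dl / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def ritland_kinship(matrix: SnpMatrix) -> np.ndarray:
    """Ritland's pairwise kinship for homozygous lines.

    With allele indicator ``x in {0, 1}`` and within-sample allele frequency
    ``p_l``, the per-locus estimator is
    ``f_l = (x_i - p_l)(x_j - p_l) / (p_l (1 - p_l))`` and the multilocus
    value is the ratio-of-sums combination with per-locus weight
    ``k_l - 1 = 1`` for biallelic loci (SPAGeDi's convention), i.e. the
    unweighted mean over loci.  Using within-sample frequencies, the mean
    off-diagonal kinship is exactly ``-1/(n-1)``.

    Monomorphic loci are undefined under this estimator and must be removed
    beforehand; their presence raises.
    """
    g = matrix.genotypes
    if not np.isin(g, (0, 1)).all():
        raise ValueError("ritland_kinship requires homozygous 0/1 calls only")
    p = g.mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic loci must be excluded before kinship estimation")
    z = (g - p) / np.sqrt(p * (1 - p))
    return (z @ z.T) / g.shape[1]


@dataclass(frozen=True)
class IbdResult:
    slope: float
    intercept: float
    p_perm: float
    n_accessions: int
    n_pairs: int
    n_perm: int


def ibd_regression(
    kinship: np.ndarray,
    coords: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    distance_transform: str = "ln",
    zero_offset_km: float = 1.0,
    alternative: str = "less",
) -> IbdResult:
    """Isolation-by-distance test: kinship on geographic distance.

    Ordinary least squares of pairwise kinship ``F_ij`` on (by default
    log-transformed) pairwise great-circle distance, over unordered pairs.
    Significance comes from permuting the geographic coordinates among
    accessions (node-label permutation, which respects the pairwise
    dependence structure) and recomputing the slope;
    ``p = (1 + #{permuted slope <= observed}) / (n_perm + 1)`` for the
    default one-tailed test of a negative slope (``alternative="greater"``
    and ``"two-sided"`` are also supported).

    Zero distances under the log transform are replaced by
    ``zero_offset_km`` with a warning.
    """
    F = np.asarray(kinship, dtype=float)
    n = F.shape[0]
    if F.shape != (n, n) or len(coords) != n:
        raise ValueError("kinship and coordinates must cover the same accessions")
    if n < 4:
        raise ValueError("need at least 4 accessions")
    if distance_transform not in ("ln", "raw"):
        raise ValueError(f"unknown distance_transform {distance_transform!r}")
    D = pairwise_geodesic(coords["lat"].to_numpy(), coords["lon"].to_numpy())
    iu = np.triu_indices(n, 1)
    if distance_transform == "ln":
        zero = D[iu] == 0
        if zero.any():
            logger.warning(
                "ibd_regression: %d zero distance pairs offset to %.3g km under ln transform",
                int(zero.sum()), zero_offset_km,
            )
        D = np.log(np.where(D == 0, zero_offset_km, D))
    y = F[iu]

    def slope_intercept(x: np.ndarray) -> tuple[float, float]:
        xm, ym = x.mean(), y.mean()
        b = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        return b, ym - b * xm

    obs_slope, intercept = slope_intercept(D[iu])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm_slopes = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        perm_slopes[k] = slope_intercept(D[np.ix_(perm, perm)][iu])[0]
    if alternative == "less":
        extreme = perm_slopes <= obs_slope
    elif alternative == "greater":
        extreme = perm_slopes >= obs_slope
    elif alternative == "two-sided":
        extreme = np.abs(perm_slopes) >= abs(obs_slope)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return IbdResult(
        slope=float(obs_slope),
        intercept=float(intercept),
        p_perm=float(p),
        n_accessions=n,
        n_pairs=len(y),
        n_perm=n_perm,
    )
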