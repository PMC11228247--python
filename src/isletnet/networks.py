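"""Heterotypic proximity networks and their degree statistics.

Cells are nodes; an undirected link joins two cells of *different* types
whose nucleus-centre distance is at most the link threshold (15, 20 or
25 μm; homotypic links are never formed).  Network membership follows the
acquisition rule: endocrine cells (α, β) must lie inside the islet rim,
immune cells (T, macrophage, myeloid) must lie inside the rim or within
an ``immune_margin`` (default 20 μm) of it.

The interaction strength between two cell types is summarized by the
average number of links per cell of a type,

    K_avg(type 1) = (# links incident to cells of type 1) / (# cells of type 1),

which for a two-type network satisfies the degree-sum identity
K_avg(A)·n_A = K_avg(B)·n_B = |E|.

On top of the plain pair networks this module implements the two
architecture-aware analyses:

* the *outer-ring / α-linked* analysis — restrict α and β cells to a band
  around the rim, split β-cells by whether they have an α neighbour
  within the threshold, and compare K_avg of α-linked versus
  non-α-linked β–immune networks;
* the *half-islet polarity* analysis — split the islet through the rim
  centroid and compare per-half proportions of each cell type.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .geometry import (
    CELL_TYPES,
    ENDOCRINE_TYPES,
    IMMUNE_TYPES,
    IsletMap,
    outer_ring,
    split_halves,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_IMMUNE_MARGIN",
    "STANDARD_THRESHOLDS",
    "ProximityNetwork",
    "DegreeSummary",
    "AlphaLinkPartition",
    "HalfSplitResult",
    "build_network",
    "k_avg",
    "degree_summary",
    "alpha_link_partition",
    "outer_ring_immune_networks",
    "half_islet_proportions",
    "degree_correlation",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 20.0  # μm
DEFAULT_IMMUNE_MARGIN = 20.0  # μm
STANDARD_THRESHOLDS = (15.0, 20.0, 25.0)


@dataclass
class ProximityNetwork:
    """A heterotypic distance-thresholded graph over a cell subset.

    ``edges`` holds unordered cell-id pairs stored as sorted tuples;
    ``distances`` the centre-to-centre distance of each edge.
    """

    nodes: dict
    edges: set
    distances: dict
    threshold: float
    member_rule: str

    def degree(self, cell_id: str) -> int:
        return sum(1 for e in self.edges if cell_id in e)

    def degrees(self) -> dict:
        deg = {cid: 0 for cid in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for cid, ctype in self.nodes.items():
            g.add_node(cid, cell_type=ctype)
        for u, v in self.edges:
            g.add_edge(u, v, distance=self.distances[(u, v)])
        return g


@dataclass(frozen=True)
class DegreeSummary:
    """Per-type K_avg plus the per-node degree table of one network."""

    k_avg: dict
    node_degrees: dict


@dataclass(frozen=True)
class AlphaLinkPartition:
    """β-cells split by whether they have an α-cell neighbour in reach."""

    alpha_linked_beta: frozenset
    non_alpha_linked_beta: frozenset


@dataclass(frozen=True)
class HalfSplitResult:
    """Per-half, per-type cell proportions for one split axis.

    ``proportions[cell_type]`` is ``(first_half, second_half)`` with the
    two values summing to 1, or ``None`` when the type is absent.
    """

    axis: str
    proportions: dict
    counts: dict


def _network_members(islet: IsletMap, types, immune_margin: float):
    """ids, types, positions of member cells under the acquisition rule."""
    ids: list[str] = []
    ctypes: list[str] = []
    pos: list[tuple] = []
    endo = [t for t in types if t in ENDOCRINE_TYPES]
    imm = [t for t in types if t in IMMUNE_TYPES]
    if endo:
        cells = islet.cells_of_type(*endo)
        d = islet.signed_distances(*endo)
        for c, di in zip(cells, d):
            if di <= 0:
                ids.append(c.cell_id)
                ctypes.append(c.cell_type)
                pos.append((c.x, c.y))
    if imm:
        cells = islet.cells_of_type(*imm)
        d = islet.signed_distances(*imm)
        for c, di in zip(cells, d):
            if di <= immune_margin:
                ids.append(c.cell_id)
                ctypes.append(c.cell_type)
                pos.append((c.x, c.y))
    return ids, ctypes, np.array(pos, dtype=float).reshape(-1, 2)


def _heterotypic_pairs(pos: np.ndarray, ctypes: list, threshold: float, method: str):
    """Index pairs (i < j) of different type within threshold (inclusive)."""
    n = len(ctypes)
    if method == "brute":
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                if ctypes[i] == ctypes[j]:
                    continue
                if math.hypot(*(pos[i] - pos[j])) <= threshold:
                    out.append((i, j))
        return out
    tree = cKDTree(pos)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    return [(int(i), int(j)) for i, j in pairs if ctypes[i] != ctypes[j]]


def build_network(
    islet: IsletMap,
    types,
    threshold: float = DEFAULT_THRESHOLD,
    immune_margin: float = DEFAULT_IMMUNE_MARGIN,
    method: str = "kdtree",
) -> ProximityNetwork:
    """Heterotypic proximity network over the requested cell types.

    Nodes are endocrine cells of the requested types inside the rim plus
    immune cells of the requested types within ``immune_margin`` of it;
    an edge joins two nodes of different type at centre distance
    <= ``threshold`` (inclusive).  ``method="brute"`` forces the O(n²)
    pairwise path (kept as the oracle the k-d-tree path is tested
    against).
    """
    unknown = set(types) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell type(s): {sorted(unknown)}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if threshold not in STANDARD_THRESHOLDS:
        warnings.warn(
            f"non-standard link threshold {threshold} μm (standard: 15/20/25)",
            stacklevel=2,
        )
    ids, ctypes, pos = _network_members(islet, types, immune_margin)
    edges = set()
    distances = {}
    for i, j in _heterotypic_pairs(pos, ctypes, threshold, method):
        key = (ids[i], ids[j]) if ids[i] <= ids[j] else (ids[j], ids[i])
        edges.add(key)
        distances[key] = float(math.hypot(*(pos[i] - pos[j])))
    rule = f"endocrine inside rim; immune within {immune_margin} μm of rim"
    return ProximityNetwork(dict(zip(ids, ctypes)), edges, distances, float(threshold), rule)


def k_avg(net: ProximityNetwork, cell_type: str) -> float:
    """Mean number of links per node of the given type; NaN if none present."""
    node_ids = [cid for cid, t in net.nodes.items() if t == cell_type]
    if not node_ids:
        logger.warning("no %s nodes in network; K_avg undefined", cell_type)
        return float("nan")
    deg = net.degrees()
    return float(sum(deg[cid] for cid in node_ids) / len(node_ids))


def degree_summary(net: ProximityNetwork) -> DegreeSummary:
    """K_avg for every type present in the network, plus per-node degrees."""
    deg = net.degrees()
    present = sorted(set(net.nodes.values()))
    ka = {}
    for t in present:
        node_ids = [cid for cid, ct in net.nodes.items() if ct == t]
        ka[t] = float(sum(deg[cid] for cid in node_ids) / len(node_ids))
    return DegreeSummary(k_avg=ka, node_degrees=deg)


def alpha_link_partition(
    islet: IsletMap,
    threshold: float = DEFAULT_THRESHOLD,
    restrict_to=None,
) -> AlphaLinkPartition:
    """Split β-cells by α-neighbourhood within the link threshold.

    A β-cell is α-linked iff at least one considered α-cell lies within
    ``threshold`` μm.  ``restrict_to`` (a cell-id set, e.g. the outer
    ring) limits both the β-cells partitioned and the α-cells that can
    confer linkage; by default the whole islet is used.
    """
    alphas = islet.cells_of_type("alpha")
    betas = islet.cells_of_type("beta")
    if restrict_to is not None:
        alphas = [c for c in alphas if c.cell_id in restrict_to]
        betas = [c for c in betas if c.cell_id in restrict_to]
    apos = np.array([(c.x, c.y) for c in alphas], dtype=float).reshape(-1, 2)
    linked = set()
    non_linked = set()
    for c in betas:
        if len(apos) and np.min(np.hypot(apos[:, 0] - c.x, apos[:, 1] - c.y)) <= threshold:
            linked.add(c.cell_id)
        else:
            non_linked.add(c.cell_id)
    return AlphaLinkPartition(frozenset(linked), frozenset(non_linked))


def _subset_pair_kavg(
    islet: IsletMap,
    beta_ids: frozenset,
    immune_type: str,
    threshold: float,
    immune_margin: float,
) -> tuple[DegreeSummary, float]:
    """β-subset vs immune network; returns its summary and K_avg of the β side."""
    betas = [c for c in islet.cells_of_type("beta") if c.cell_id in beta_ids]
    imm_cells = islet.cells_of_type(immune_type)
    if imm_cells:
        d = islet.signed_distances(immune_type)
        imm_cells = [c for c, di in zip(imm_cells, d) if di <= immune_margin]
    nodes = {c.cell_id: c.cell_type for c in betas + imm_cells}
    bpos = np.array([(c.x, c.y) for c in betas], dtype=float).reshape(-1, 2)
    ipos = np.array([(c.x, c.y) for c in imm_cells], dtype=float).reshape(-1, 2)
    edges = set()
    distances = {}
    if len(bpos) and len(ipos):
        dmat = np.hypot(
            bpos[:, 0:1] - ipos[None, :, 0], bpos[:, 1:2] - ipos[None, :, 1]
        )
        for bi, ii in zip(*np.nonzero(dmat <= threshold)):
            u, v = betas[bi].cell_id, imm_cells[ii].cell_id
            key = (u, v) if u <= v else (v, u)
            edges.add(key)
            distances[key] = float(dmat[bi, ii])
    net = ProximityNetwork(
        nodes, edges, distances, float(threshold),
        f"β subset ({len(betas)}) vs {immune_type} within {immune_margin} μm",
    )
    summary = degree_summary(net) if nodes else DegreeSummary({}, {})
    kb = summary.k_avg.get("beta", float("nan")) if betas else float("nan")
    if not betas:
        logger.debug("empty β subset in islet %s; K_avg undefined", islet.islet_id)
    elif not imm_cells:
        kb = 0.0
    return summary, kb


def outer_ring_immune_networks(
    islet: IsletMap,
    immune_type: str,
    threshold: float = DEFAULT_THRESHOLD,
    band: float = 20.0,
    immune_margin: float = DEFAULT_IMMUNE_MARGIN,
):
    """α-linked vs non-α-linked β–immune networks in the outer ring.

    α- and β-cells are restricted to the outer ring (|rim distance| <=
    band); ring β-cells are partitioned by α-linkage within the ring;
    two β–immune networks are built with the standard immune membership
    rule.  Returns ``(summary_linked, summary_non_linked, kavg_linked,
    kavg_non_linked)``; an empty β subset yields NaN for that side.
    """
    if immune_type not in IMMUNE_TYPES:
        raise ValueError(f"{immune_type!r} is not an immune cell type")
    ring = outer_ring(islet, band)
    part = alpha_link_partition(islet, threshold, restrict_to=ring)
    s_linked, k_linked = _subset_pair_kavg(
        islet, part.alpha_linked_beta, immune_type, threshold, immune_margin
    )
    s_non, k_non = _subset_pair_kavg(
        islet, part.non_alpha_linked_beta, immune_type, threshold, immune_margin
    )
    return s_linked, s_non, k_linked, k_non


def half_islet_proportions(
    islet: IsletMap, axis: str = "vertical", band: float = 20.0
) -> HalfSplitResult:
    """Per-half, per-type cell proportions across a centroid split plane.

    Considered cells are endocrine cells plus immune cells within
    ``band`` μm of the rim.  For each type present, the proportion in
    each half is that half's count divided by the type total (the two
    proportions sum to 1); absent types map to ``None``.
    """
    first, second = split_halves(islet, axis, band)
    counts = {}
    proportions = {}
    by_id = {c.cell_id: c.cell_type for c in islet.cells}
    for t in CELL_TYPES:
        n1 = sum(1 for cid in first if by_id[cid] == t)
        n2 = sum(1 for cid in second if by_id[cid] == t)
        counts[t] = (n1, n2)
        total = n1 + n2
        proportions[t] = (n1 / total, n2 / total) if total else None
    return HalfSplitResult(axis=axis, proportions=proportions, counts=counts)


def half_polarity_points(
    cohort: list[IsletMap],
    immune_type: str,
    axis: str = "vertical",
    band: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-islet (%α, %immune) of the first half, for polarity regression.

    Each islet contributes one point: the proportions of α and of the
    immune type falling in the first (left/lower) half.  The second
    half's proportions are their complements, so adding them would only
    duplicate every point mirrored about (0.5, 0.5) and understate the
    regression standard error; one half per islet keeps the points
    independent.  Islets missing either type are skipped.
    """
    xs, ys = [], []
    for islet in cohort:
        res = half_islet_proportions(islet, axis, band)
        pa = res.proportions["alpha"]
        pi = res.proportions[immune_type]
        if pa is None or pi is None:
            continue
        xs.append(pa[0])
        ys.append(pi[0])
    return np.asarray(xs), np.asarray(ys)


def degree_correlation(
    cohort: list[IsletMap],
    pair_x: tuple[str, str],
    pair_y: tuple[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    immune_margin: float = DEFAULT_IMMUNE_MARGIN,
):
    """Regress per-islet K_avg(β) of network y on that of network x.

    ``pair_x`` / ``pair_y`` are ``("beta", immune_type)`` pairs.  Islets
    where either K_avg is undefined are dropped listwise.  Returns a dict
    with slope, intercept, r2, p and n; degenerate variance is flagged.
    """
    xs, ys = [], []
    for islet in cohort:
        kx = k_avg(build_network(islet, set(pair_x), threshold, immune_margin), pair_x[0])
        ky = k_avg(build_network(islet, set(pair_y), threshold, immune_margin), pair_y[0])
        if not (math.isnan(kx) or math.isnan(ky)):
            xs.append(kx)
            ys.append(ky)
    if len(xs) < 3:
        raise ValueError("need >= 3 islets with defined K_avg for both pairs")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return {"slope": float("nan"), "intercept": float("nan"), "r2": float("nan"),
                "p": float("nan"), "n": len(xs), "degenerate": True}
    res = linregress(xs, ys)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "p": float(res.pvalue), "n": len(xs),
            "degenerate": False}
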