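"""Neurite-outgrowth morphometry from two-channel neuron images.

From a nuclei channel and a neurite-marker channel the module derives six
per-cell phenotypes used in high-content neurotoxicity screening:

* maximum neurite length — longest root-to-tip geodesic on the soma,
* total neurite length — summed length of all neurite branches,
* number of extremities — neurite endpoints,
* number of roots — attachment points on the soma boundary,
* number of segments — branch-point-free skeleton paths,
* number of nodes — branch points outside the soma.

The chain is: nuclei segmentation (Otsu + watershed split) and marker-
positivity QC -> soma mask (morphological opening of the marker mask keeps
cell bodies, drops thin neurites) -> neurite mask -> 1-px skeleton ->
soma-rooted graph with geodesic edge lengths (1 per axial step, sqrt(2) per
diagonal) -> phenotypes. "Segment" here means a maximal branch-point-free
path, the standard morphometric reading; treated-vs-control comparisons are
invariant to that convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import dilation, disk, opening, skeletonize
from skimage.segmentation import expand_labels, watershed

from .synth import NeuronImage

__all__ = [
    "MorphometryParams",
    "CellSegmentation",
    "MorphologyGraph",
    "NeuritePhenotypes",
    "segment_cells",
    "segment_neurites",
    "skeletonize_and_graph",
    "compute_phenotypes",
    "analyze_image",
]

logger = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class MorphometryParams:
    """Tunable segmentation/graph parameters.

    ``soma_open_radius`` is the opening radius separating cell bodies from
    thin neurites; ``spur_length`` (px) removes short skeleton side-branches
    that are thinning artifacts; ``positive_factor`` sets how far above
    background the marker signal around a nucleus must be to call the cell
    marker-positive.
    """

    nucleus_min_area: int = 12
    nucleus_split_distance: int = 6
    marker_offset: float = 0.0
    positive_factor: float = 2.0
    soma_open_radius: int = 3
    neurite_min_size: int = 10
    spur_length: float = 5.0
    root_reach: float = 5.0


@dataclass
class CellSegmentation:
    """Labelled nuclei and somas plus the marker-positivity QC statistic."""

    nuclei_labels: np.ndarray
    soma_labels: np.ndarray
    positive: dict[int, bool]
    marker_positive_fraction: float  # NaN when no nuclei were found

    @property
    def n_cells(self) -> int:
        return int(self.soma_labels.max())


def segment_cells(
    image: NeuronImage, params: MorphometryParams | None = None
) -> CellSegmentation:
    """Detect nuclei, call marker positivity, and derive soma regions.

    Nuclei come from Otsu thresholding of the nuclei channel with a
    distance-transform watershed to split touching pairs. A nucleus is
    marker-positive when the median marker intensity in a dilated ring
    around it exceeds ``positive_factor`` x the image background. Somas are
    the thick (opening-surviving) marker blobs, watershed-assigned to the
    marker-positive nuclei they contain. A blank image yields zero cells and
    an undefined (NaN) positive fraction.
    """
    p = params or MorphometryParams()
    nuc = np.asarray(image.nuclei, dtype=float)
    mark = np.asarray(image.marker, dtype=float)
    if nuc.max() <= 0:
        z = np.zeros(nuc.shape, dtype=np.int32)
        logger.warning("segment_cells: blank nuclei channel")
        return CellSegmentation(z, z.copy(), {}, float("nan"))

    nuc_mask = _drop_small(nuc > threshold_otsu(nuc), p.nucleus_min_area)
    dist = ndimage.distance_transform_edt(nuc_mask)
    # seeds: local maxima of the distance map, one per nucleus
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        dist, min_distance=p.nucleus_split_distance, labels=sk_label(nuc_mask)
    )
    seeds = np.zeros(nuc.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    nuclei_labels = watershed(-dist, markers=seeds, mask=nuc_mask)

    background = float(np.median(mark))
    positive: dict[int, bool] = {}
    for lbl in range(1, nuclei_labels.max() + 1):
        region = nuclei_labels == lbl
        ring = dilation(region, footprint=disk(3)) & ~region
        med = float(np.median(mark[ring])) if ring.any() else 0.0
        positive[lbl] = med > p.positive_factor * max(background, 1e-6)
    frac = (
        float(np.mean(list(positive.values()))) if positive else float("nan")
    )

    soma_mask = np.zeros(nuc.shape, dtype=bool)
    if mark.max() > 0:
        thr = threshold_otsu(mark) + p.marker_offset
        soma_mask = opening(mark > thr, footprint=disk(p.soma_open_radius))
    pos_seeds = np.where(
        np.isin(nuclei_labels, [l for l, ok in positive.items() if ok]),
        nuclei_labels,
        0,
    ).astype(np.int32)
    soma_labels = watershed(
        -ndimage.distance_transform_edt(soma_mask),
        markers=pos_seeds * soma_mask,
        mask=soma_mask,
    )
    return CellSegmentation(nuclei_labels, soma_labels, positive, frac)


def segment_neurites(
    image: NeuronImage,
    params: MorphometryParams | None = None,
    soma_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Binary mask of marker-positive thin structures, soma interiors excluded.

    Otsu threshold (plus configurable offset) on the marker channel, small
    specks removed; pixels inside detected somas are cleared so the skeleton
    terminates at the soma boundary. Deterministic for fixed parameters; a
    blank channel yields an empty mask.
    """
    p = params or MorphometryParams()
    mark = np.asarray(image.marker, dtype=float)
    if mark.max() <= 0:
        return np.zeros(mark.shape, dtype=bool)
    mask = _drop_small(mark > (threshold_otsu(mark) + p.marker_offset),
                       p.neurite_min_size)
    if soma_labels is not None:
        mask &= soma_labels == 0
    return mask


# --------------------------------------------------------------------------
# Skeleton graph
# --------------------------------------------------------------------------

def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


_OFFSETS_AXIAL = [(-1, 0), (0, -1), (0, 1), (1, 0)]
_OFFSETS_DIAG = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class MorphologyGraph:
    """Soma-rooted skeleton topology.

    ``topo`` is a multigraph whose nodes are typed ``root`` / ``node`` /
    ``extremity`` clusters of skeleton pixels and whose edges carry geodesic
    ``length`` in pixels. Root nodes carry the id of the soma they attach
    to. ``soma_ids`` lists every segmented soma, including neurite-free ones.
    """

    topo: nx.MultiGraph
    soma_ids: list[int]
    skeleton: np.ndarray | None = None

    def roots_of(self, soma: int) -> list:
        return [
            n for n, d in self.topo.nodes(data=True)
            if d["kind"] == "root" and d.get("soma") == soma
        ]


def _pixel_graph(skel: np.ndarray) -> tuple[nx.Graph, np.ndarray]:
    """8-connected pixel graph of a skeleton with the standard reduction:
    a diagonal link is dropped when the two pixels share an axial skeleton
    neighbour, so staircases do not form spurious triangles."""
    g = nx.Graph()
    coords = np.argwhere(skel)
    for r, c in coords:
        g.add_node((int(r), int(c)))
    h, w = skel.shape

    def inside(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and skel[r, c]

    for r, c in coords:
        r, c = int(r), int(c)
        for dr, dc in _OFFSETS_AXIAL:
            if inside(r + dr, c + dc):
                g.add_edge((r, c), (r + dr, c + dc), weight=1.0)
        for dr, dc in _OFFSETS_DIAG:
            if inside(r + dr, c + dc) and not (
                inside(r + dr, c) or inside(r, c + dc)
            ):
                g.add_edge((r, c), (r + dr, c + dc), weight=_SQRT2)
    return g, coords


def skeletonize_and_graph(
    neurite_mask: np.ndarray,
    soma_labels: np.ndarray,
    params: MorphometryParams | None = None,
) -> MorphologyGraph:
    """Skeletonize the neurite mask and build the soma-rooted topology graph.

    Skeleton junction/endpoint pixels are clustered into vertices; maximal
    branch-free pixel chains become edges with geodesic length. Skeleton
    pixels within ``root_reach`` of a soma form that tree's root vertex (a
    chain touching two somas is assigned to the nearer one). Spur branches
    shorter than ``spur_length`` are pruned, leftover degree-2 junctions are
    dissolved, and any skeleton loop is broken at its edge farthest from the
    soma so every tree is acyclic.
    """
    p = params or MorphometryParams()
    if neurite_mask.shape != soma_labels.shape:
        raise ValueError("mask shapes differ")
    skel = skeletonize(neurite_mask)
    g, coords = _pixel_graph(skel)

    # root pixels: nearest-soma assignment within reach
    near = expand_labels(soma_labels, distance=p.root_reach)
    root_soma = {
        (int(r), int(c)): int(near[r, c]) for r, c in coords if near[r, c] > 0
    }
    # geodesic lengths should start at the soma boundary, but the skeleton
    # retracts and the root cluster swallows the first few chain pixels;
    # edges leaving a root cluster are extended by the start pixel's
    # distance to the soma
    soma_dist = ndimage.distance_transform_edt(soma_labels == 0)

    vertex_px = {n for n in g if g.degree(n) != 2} | set(root_soma)
    # Cluster vertex pixels into graph vertices: adjacent vertex pixels
    # always merge, and junction/root pixels additionally merge when a short
    # skeleton path (<= 5 steps) connects them — thinning can split one
    # branch point into two junction pixels a few px apart, while genuine
    # vertices of different neurites are never short-path connected.
    junctionish = {px for px in vertex_px if px in root_soma or g.degree(px) >= 3}
    aux = nx.Graph()
    aux.add_nodes_from(vertex_px)
    for u, v in g.edges:
        if u in vertex_px and v in vertex_px:
            aux.add_edge(u, v)
    for px in junctionish:
        near = nx.single_source_shortest_path_length(g, px, cutoff=5)
        for q, d in near.items():
            if q is not px and q in junctionish:
                aux.add_edge(px, q)
    clusters = list(nx.connected_components(aux))
    cl_of: dict[tuple[int, int], int] = {}
    for i, cl in enumerate(clusters):
        for px in cl:
            cl_of[px] = i

    topo = nx.MultiGraph()
    for i, cl in enumerate(clusters):
        somas = {root_soma[px] for px in cl if px in root_soma}
        if somas:
            kind, soma = "root", sorted(somas)[0]
            if len(somas) > 1:
                logger.warning("root cluster touches somas %s; assigned to %s",
                               sorted(somas), soma)
        else:
            kind, soma = "node", None  # retyped later by degree
        topo.add_node(i, kind=kind, soma=soma, pixels=frozenset(cl))

    def _root_extension(cluster_id: int, px: tuple[int, int]) -> float:
        if topo.nodes[cluster_id]["kind"] != "root":
            return 0.0
        return float(soma_dist[px])

    # trace branch-free chains between vertex clusters
    seen: set[tuple] = set()
    for i, cl in enumerate(clusters):
        for start in cl:
            for nxt in g.neighbors(start):
                if nxt in vertex_px:
                    if cl_of[nxt] != i:
                        key = (min(start, nxt), max(start, nxt))
                        if key not in seen:
                            seen.add(key)
                            length = (
                                g.edges[start, nxt]["weight"]
                                + _root_extension(i, start)
                                + _root_extension(cl_of[nxt], nxt)
                            )
                            topo.add_edge(i, cl_of[nxt], length=length)
                    continue
                if (start, nxt) in seen:
                    continue
                length = g.edges[start, nxt]["weight"] + _root_extension(i, start)
                prev, cur = start, nxt
                while cur not in vertex_px:
                    nbrs = [q for q in g.neighbors(cur) if q != prev]
                    if not nbrs:  # isolated dangling chain end
                        break
                    length += g.edges[cur, nbrs[0]]["weight"]
                    prev, cur = cur, nbrs[0]
                if cur in vertex_px:
                    seen.add((start, nxt))
                    seen.add((cur, prev))
                    topo.add_edge(i, cl_of[cur],
                                  length=length + _root_extension(cl_of[cur], cur))

    _assign_endpoint_kinds(topo)
    _break_cycles(topo)
    _prune_spurs(topo, p.spur_length)
    _break_cycles(topo)  # dissolving pass-throughs can recreate parallel edges
    soma_ids = sorted(int(v) for v in np.unique(soma_labels) if v > 0)
    return MorphologyGraph(topo=topo, soma_ids=soma_ids, skeleton=skel)


def _assign_endpoint_kinds(topo: nx.MultiGraph) -> None:
    for n, d in topo.nodes(data=True):
        if d["kind"] == "root":
            continue
        d["kind"] = "extremity" if topo.degree(n) <= 1 else "node"


def _root_distances(topo: nx.MultiGraph) -> dict:
    roots = [n for n, d in topo.nodes(data=True) if d["kind"] == "root"]
    dist: dict = {}
    for r in roots:
        for n, l in nx.single_source_dijkstra_path_length(
            topo, r, weight="length"
        ).items():
            if n not in dist or l < dist[n]:
                dist[n] = l
    return dist


def _break_cycles(topo: nx.MultiGraph) -> None:
    """Remove self-loops, then break remaining cycles at the edge farthest
    from the soma (largest root distance of its endpoints)."""
    for n, m, k in list(nx.selfloop_edges(topo, keys=True)):
        topo.remove_edge(n, m, key=k)
    while True:
        try:
            cycle = nx.find_cycle(topo)
        except nx.NetworkXNoCycle:
            return
        dist = _root_distances(topo)
        far = max(
            cycle,
            key=lambda e: max(dist.get(e[0], 0.0), dist.get(e[1], 0.0)),
        )
        topo.remove_edge(far[0], far[1], key=far[2])
        _assign_endpoint_kinds(topo)


def _prune_spurs(topo: nx.MultiGraph, spur_length: float) -> None:
    """Iteratively drop short artifact side-branches, then dissolve the
    degree-2 junctions they leave behind."""
    changed = True
    while changed:
        changed = False
        for n in list(topo.nodes):
            d = topo.nodes[n]
            if d["kind"] != "extremity" or topo.degree(n) != 1:
                continue
            (u, v, k) = next(iter(topo.edges(n, keys=True)))
            other = v if u == n else u
            if (
                topo.edges[u, v, k]["length"] < spur_length
                and topo.nodes[other]["kind"] == "node"
            ):
                topo.remove_node(n)
                changed = True
        # dissolve pass: junction clusters reduced to pass-throughs
        for n in list(topo.nodes):
            if topo.nodes[n]["kind"] != "node":
                continue
            deg = topo.degree(n)
            if deg == 0:
                topo.remove_node(n)
                changed = True
            elif deg == 1:
                topo.nodes[n]["kind"] = "extremity"
                changed = True
            elif deg == 2:
                (e1, e2) = list(topo.edges(n, keys=True, data=True))
                a = e1[1] if e1[0] == n else e1[0]
                b = e2[1] if e2[0] == n else e2[0]
                topo.add_edge(a, b, length=e1[3]["length"] + e2[3]["length"])
                topo.remove_node(n)
                changed = True


# --------------------------------------------------------------------------
# Phenotypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuritePhenotypes:
    """The six neurite-outgrowth phenotypes of one soma (lengths in px)."""

    max_neurite_length: float
    total_neurite_length: float
    n_extremities: int
    n_roots: int
    n_segments: int
    n_nodes: int

    @classmethod
    def zero(cls) -> "NeuritePhenotypes":
        return cls(0.0, 0.0, 0, 0, 0, 0)

    def as_dict(self) -> dict:
        return {
            "max_neurite_length": self.max_neurite_length,
            "total_neurite_length": self.total_neurite_length,
            "n_extremities": self.n_extremities,
            "n_roots": self.n_roots,
            "n_segments": self.n_segments,
            "n_nodes": self.n_nodes,
        }


def compute_phenotypes(graph: MorphologyGraph) -> pd.DataFrame:
    """Per-soma phenotype table (one row per segmented soma).

    Components of the topology graph are assigned to the soma their root
    vertex touches; somas without neurites get all-zero phenotypes and stay
    in the table (they count toward well means). Maximum neurite length is
    the longest root-to-extremity geodesic.
    """
    topo = graph.topo
    per_soma = {s: {"edges": set(), "nodes": set()} for s in graph.soma_ids}
    for comp in nx.connected_components(topo):
        root_somas = sorted(
            {
                topo.nodes[n]["soma"]
                for n in comp
                if topo.nodes[n]["kind"] == "root"
            }
        )
        if not root_somas:
            continue  # debris not attached to any soma
        soma = root_somas[0]
        if soma not in per_soma:
            per_soma[soma] = {"edges": set(), "nodes": set()}
        for n in comp:
            per_soma[soma]["nodes"].add(n)
            for e in topo.edges(n, keys=True):
                per_soma[soma]["edges"].add(
                    (min(e[0], e[1]), max(e[0], e[1]), e[2])
                )

    rows = []
    for soma in sorted(per_soma):
        nodes = per_soma[soma]["nodes"]
        edges = per_soma[soma]["edges"]
        total = float(
            sum(topo.edges[u, v, k]["length"] for (u, v, k) in edges)
        )
        kinds = [topo.nodes[n]["kind"] for n in nodes]
        roots = [n for n in nodes if topo.nodes[n]["kind"] == "root"]
        max_len = 0.0
        for r in roots:
            dl = nx.single_source_dijkstra_path_length(topo, r, weight="length")
            for n, l in dl.items():
                if topo.nodes[n]["kind"] == "extremity" and l > max_len:
                    max_len = float(l)
        ph = NeuritePhenotypes(
            max_neurite_length=max_len,
            total_neurite_length=total,
            n_extremities=kinds.count("extremity"),
            n_roots=len(roots),
            n_segments=len(edges),
            n_nodes=kinds.count("node"),
        )
        rows.append({"soma": soma, **ph.as_dict()})
    return pd.DataFrame(
        rows,
        columns=[
            "soma", "max_neurite_length", "total_neurite_length",
            "n_extremities", "n_roots", "n_segments", "n_nodes",
        ],
    )


def aggregate_phenotypes(per_cell: pd.DataFrame) -> pd.Series:
    """Well/image aggregate: mean over somas (zero-phenotype somas included)."""
    cols = [c for c in per_cell.columns if c != "soma"]
    if per_cell.empty:
        return pd.Series({c: 0.0 for c in cols})
    return per_cell[cols].mean()


def analyze_image(
    image: NeuronImage, params: MorphometryParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full single-image morphometry: segmentation -> graph -> phenotypes.

    Returns the per-soma phenotype table and a QC dict (cell count and
    marker-positive fraction).
    """
    p = params or MorphometryParams()
    seg = segment_cells(image, p)
    mask = segment_neurites(image, p, soma_labels=seg.soma_labels)
    graph = skeletonize_and_graph(mask, seg.soma_labels, p)
    table = compute_phenotypes(graph)
    qc = {
        "n_cells": seg.n_cells,
        "marker_positive_fraction": seg.marker_positive_fraction,
    }
    return table, qc
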