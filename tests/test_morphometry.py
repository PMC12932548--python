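"""Segmentation, skeleton-graph construction and phenotype extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation

from neurotox import (
    MorphologySpec,
    MorphometryParams,
    NeuronImage,
    analyze_image,
    compute_phenotypes,
    generate_neuron_image,
    segment_cells,
    segment_neurites,
    skeletonize_and_graph,
)
from neurotox.morphometry import MorphologyGraph
from neurotox.synth import _NUCLEUS_VALUE, _SOMA_VALUE, _STROKE_VALUE


def _blank(shape=(256, 256)):
    return (
        np.zeros(shape, dtype=np.float32),
        np.zeros(shape, dtype=np.float32),
    )


def _add_soma(nuclei, marker, center, radius=12):
    rr, cc = draw_disk(center, int(0.6 * radius), shape=nuclei.shape)
    nuclei[rr, cc] = _NUCLEUS_VALUE
    rr, cc = draw_disk(center, radius, shape=marker.shape)
    marker[rr, cc] = _SOMA_VALUE


def _add_stroke(marker, p0, p1):
    stroke = np.zeros(marker.shape, dtype=bool)
    rr, cc = draw_line(*p0, *p1)
    stroke[rr, cc] = True
    thick = dilation(stroke, footprint=np.ones((2, 2), dtype=bool))
    marker[thick] = np.maximum(marker[thick], _STROKE_VALUE)


class TestSegmentation:
    def test_blank_image_zero_cells_undefined_fraction(self):
        nuclei, marker = _blank()
        seg = segment_cells(NeuronImage(nuclei=nuclei, marker=marker))
        assert seg.n_cells == 0
        assert np.isnan(seg.marker_positive_fraction)

    def test_all_positive_discs(self):
        img, gt = generate_neuron_image(MorphologySpec(n_somas=5, seed=2))
        seg = segment_cells(img)
        assert seg.n_cells == 5
        assert seg.marker_positive_fraction == 1.0

    def test_half_positive_fraction(self):
        spec = MorphologySpec(n_somas=10, marker_positive_fraction=0.5, seed=3)
        img, gt = generate_neuron_image(spec)
        seg = segment_cells(img)
        assert seg.marker_positive_fraction == pytest.approx(0.5)

    def test_touching_nuclei_split_by_watershed(self):
        nuclei, marker = _blank()
        _add_soma(nuclei, marker, (120, 110))
        _add_soma(nuclei, marker, (120, 133))  # soma discs touch, nuclei don't
        seg = segment_cells(NeuronImage(nuclei=nuclei, marker=marker))
        assert seg.n_cells == 2

    def test_neurite_mask_recovers_strokes(self):
        img, _ = generate_neuron_image(MorphologySpec(seed=4))
        truth = img.marker == _STROKE_VALUE
        seg = segment_cells(img)
        mask = segment_neurites(img, soma_labels=seg.soma_labels)
        inter = np.logical_and(mask, truth).sum()
        union = np.logical_or(mask, truth).sum()
        assert inter / union >= 0.9

    def test_neurite_mask_robust_to_noise(self):
        img, _ = generate_neuron_image(MorphologySpec(seed=5))
        truth = img.marker == _STROKE_VALUE
        rng = np.random.default_rng(0)
        noisy = NeuronImage(
            nuclei=img.nuclei,
            marker=np.clip(
                img.marker + rng.normal(0, 0.1 * _STROKE_VALUE, img.marker.shape), 0, None
            ).astype(np.float32),
        )
        seg = segment_cells(noisy)
        mask = segment_neurites(noisy, soma_labels=seg.soma_labels)
        inter = np.logical_and(mask, truth).sum()
        union = np.logical_or(mask, truth).sum()
        assert inter / union >= 0.8

    def test_blank_marker_gives_empty_mask(self):
        nuclei, marker = _blank()
        mask = segment_neurites(NeuronImage(nuclei=nuclei, marker=marker))
        assert not mask.any()


class TestSkeletonGraph:
    def test_straight_stroke_topology_and_length(self):
        nuclei, marker = _blank()
        _add_soma(nuclei, marker, (128, 60))
        _add_stroke(marker, (128, 73), (128, 172))  # 100 px horizontal
        img = NeuronImage(nuclei=nuclei, marker=marker)
        table, _ = analyze_image(img)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_roots == 1
        assert row.n_nodes == 0
        assert row.n_extremities == 1
        assert row.n_segments == 1
        assert row.total_neurite_length == pytest.approx(100, abs=5)
        assert row.max_neurite_length == pytest.approx(100, abs=5)

    def test_y_tree_topology(self):
        nuclei, marker = _blank()
        _add_soma(nuclei, marker, (128, 50))
        _add_stroke(marker, (128, 63), (128, 120))
        _add_stroke(marker, (128, 120), (93, 165))
        _add_stroke(marker, (128, 120), (163, 165))
        img = NeuronImage(nuclei=nuclei, marker=marker)
        table, _ = analyze_image(img)
        row = table.iloc[0]
        assert (row.n_roots, row.n_nodes, row.n_extremities, row.n_segments) == (
            1, 1, 2, 3,
        )

    def test_empty_mask_gives_empty_graph(self):
        mask = np.zeros((64, 64), dtype=bool)
        graph = skeletonize_and_graph(mask, np.zeros((64, 64), dtype=np.int32))
        assert graph.topo.number_of_nodes() == 0

    def test_phenotype_arithmetic_on_synthetic_tree(self):
        # root--(50)--node--(30/40)--tips: total 120, max 50+40=90
        topo = nx.MultiGraph()
        topo.add_node(0, kind="root", soma=1, pixels=frozenset())
        topo.add_node(1, kind="node", soma=None, pixels=frozenset())
        topo.add_node(2, kind="extremity", soma=None, pixels=frozenset())
        topo.add_node(3, kind="extremity", soma=None, pixels=frozenset())
        topo.add_edge(0, 1, length=50.0)
        topo.add_edge(1, 2, length=30.0)
        topo.add_edge(1, 3, length=40.0)
        table = compute_phenotypes(MorphologyGraph(topo=topo, soma_ids=[1]))
        row = table.iloc[0]
        assert row.total_neurite_length == 120.0
        assert row.max_neurite_length == 90.0
        assert (row.n_roots, row.n_nodes, row.n_extremities, row.n_segments) == (
            1, 1, 2, 3,
        )


class TestRecovery:
    @pytest.mark.parametrize("seed", range(8))
    def test_counts_exact_and_lengths_close(self, seed):
        img, gt = generate_neuron_image(MorphologySpec(seed=seed))
        table, qc = analyze_image(img)
        gdf = pd.DataFrame(
            [
                {
                    "n_roots": s.n_roots, "n_nodes": s.n_nodes,
                    "n_extremities": s.n_extremities, "n_segments": s.n_segments,
                    "total": s.total_length, "max": s.max_length,
                }
                for s in gt.somas if s.marker_positive
            ]
        )
        for col in ("n_roots", "n_nodes", "n_extremities", "n_segments"):
            assert int(table[col].sum()) == int(gdf[col].sum())
        assert table["total_neurite_length"].sum() == pytest.approx(
            gdf["total"].sum(), rel=0.10
        )
        assert table["max_neurite_length"].sum() == pytest.approx(
            gdf["max"].sum(), rel=0.10
        )

    def test_euler_relation_on_detected_trees(self):
        img, _ = generate_neuron_image(MorphologySpec(seed=9))
        table, _ = analyze_image(img)
        # binary trees: segments = roots + 2*nodes, extremities = roots + nodes
        assert (table.n_segments == table.n_roots + 2 * table.n_nodes).all()
        assert (table.n_extremities == table.n_roots + table.n_nodes).all()

    def test_rotation_invariance(self):
        img, _ = generate_neuron_image(MorphologySpec(seed=6))
        rot = NeuronImage(
            nuclei=np.ascontiguousarray(np.rot90(img.nuclei)),
            marker=np.ascontiguousarray(np.rot90(img.marker)),
        )
        a, _ = analyze_image(img)
        b, _ = analyze_image(rot)
        for col in ("n_roots", "n_nodes", "n_extremities", "n_segments"):
            assert int(a[col].sum()) == int(b[col].sum())
        assert a["total_neurite_length"].sum() == pytest.approx(
            b["total_neurite_length"].sum(), rel=0.02
        )

    def test_determinism(self):
        img, _ = generate_neuron_image(MorphologySpec(seed=8))
        a, _ = analyze_image(img)
        b, _ = analyze_image(img)
        pd.testing.assert_frame_equal(a, b)
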