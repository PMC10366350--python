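"""Generator behaviour: geometry, determinism, planted-effect realisation."""

import numpy as np
import pandas as pd
import pytest
import scipy.spatial

from spatprox import (
    InvalidParameterError,
    SimulationConfig,
    build_network,
    make_grid,
    pair_edge_counts,
    simulate_cohort,
    simulate_deconv,
    simulate_expression,
    simulate_labels,
)
from spatprox.deconv_metrics import shannon_index
from spatprox.synthdata import default_lr_catalog


class TestMakeGrid:
    def test_hex_geometry_without_jitter(self):
        g = make_grid(2, 2, 1.0, 0.0, seed=0)
        assert len(g) == 4
        row0 = g[g.spot_id.str.startswith("spot_000")]
        row1 = g[g.spot_id.str.startswith("spot_001")]
        # second row offset by spacing/2 in x
        assert np.allclose(sorted(row1.x) , np.array(sorted(row0.x)) + 0.5)
        # nearest-neighbour distance within a row is the spacing
        assert np.isclose(row0.x.max() - row0.x.min(), 1.0)
        # offset packing: rows one spacing apart
        assert np.isclose(row1.y.iloc[0] - row0.y.iloc[0], 1.0)

    def test_seed_determinism_with_jitter(self):
        a = make_grid(5, 5, 1.0, 0.1, seed=7)
        b = make_grid(5, 5, 1.0, 0.1, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_nearest_neighbour_distance(self):
        g = make_grid(10, 10, 1.0, 0.05, seed=1)
        assert len(g) == 100
        # independent brute-force all-pairs scan
        xy = g[["x", "y"]].to_numpy()
        D = scipy.spatial.distance.cdist(xy, xy)
        np.fill_diagonal(D, np.inf)
        assert abs(D.min(axis=1).mean() - 1.0) < 0.05

    def test_invalid_spacing(self):
        with pytest.raises(InvalidParameterError):
            make_grid(3, 3, 0.0, 0.0, seed=0)


class TestSimulateLabels:
    def test_zero_mixing_is_identity(self):
        g = make_grid(12, 12, 1.0, 0.05, seed=3)
        base = simulate_labels(g, 4, 2.5, [], seed=9)
        planted = simulate_labels(g, 4, 2.5, [(0, 1, 0.0)], seed=9)
        assert np.array_equal(base, planted)

    def test_single_type_degenerate(self):
        g = make_grid(4, 4, 1.0, 0.0, seed=0)
        labels = simulate_labels(g, 1, 2.0, [], seed=0)
        assert np.all(labels == 0)

    def test_out_of_range_type_rejected(self):
        g = make_grid(4, 4, 1.0, 0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_labels(g, 3, 2.0, [(0, 5, 0.5)], seed=0)

    def test_planted_mixing_raises_adjacency(self):
        """s = 0.8 increases planted-pair Delaunay adjacency vs s = 0."""
        wins = 0
        for seed in range(20):
            g = make_grid(16, 16, 1.0, 0.05, seed=seed)
            net = build_network(g)
            base = simulate_labels(g, 4, 2.0, [(0, 1, 0.0)], seed=seed)
            mixed = simulate_labels(g, 4, 2.0, [(0, 1, 0.8)], seed=seed)
            c_base = pair_edge_counts(net, base).get((0, 1), 0)
            c_mix = pair_edge_counts(net, mixed).get((0, 1), 0)
            # independent brute-force adjacency scan
            brute = sum(
                1
                for u, v in net.edges
                if {mixed[u], mixed[v]} == {0, 1}
            )
            assert brute == c_mix
            wins += c_mix > c_base
        assert wins == 20


class TestSimulateDeconv:
    def test_rows_on_simplex(self):
        labels = np.random.default_rng(0).integers(0, 5, 300)
        d = simulate_deconv(labels, [0.5] * 5, seed=1)
        v = d.to_numpy()
        assert np.allclose(v.sum(axis=1), 1.0, atol=1e-9)
        assert v.min() >= 0 and v.max() <= 1

    def test_large_alpha_approaches_uniform(self):
        labels = np.zeros(2000, dtype=int)
        d = simulate_deconv(labels, [1000.0] * 4, seed=2, dominance=1.0)
        assert np.abs(d.mean(axis=0) - 0.25).max() < 0.02

    def test_seed_determinism(self):
        labels = np.arange(10) % 3
        a = simulate_deconv(labels, [1.0, 2.0, 3.0], seed=5)
        b = simulate_deconv(labels, [1.0, 2.0, 3.0], seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_deconv(np.zeros(4, dtype=int), [1.0, 0.0], seed=0)


class TestSimulateExpression:
    @staticmethod
    def _setup(seed, n_types=3):
        g = make_grid(12, 12, 1.0, 0.05, seed=seed)
        labels = simulate_labels(g, n_types, 2.5, [], seed=seed)
        return g, labels, build_network(g)

    def test_unit_effect_is_identity(self):
        g, labels, net = self._setup(4)
        cat = [("G0000", "G0001")]
        a, _, _ = simulate_expression(labels, net, cat, [], 20, 2.0, 2.0, seed=8)
        b, _, _ = simulate_expression(
            labels, net, cat, [(0, 1, "G0000", "G0001", 1.0)], 20, 2.0, 2.0, seed=8
        )
        assert (a != b).nnz == 0

    def test_zero_mean_gives_zero_matrix(self):
        g, labels, net = self._setup(5)
        counts, _, _ = simulate_expression(
            labels, net, [], [], 15, 0.0, 2.0, seed=1
        )
        assert counts.nnz == 0

    def test_gene_outside_catalogue_rejected(self):
        g, labels, net = self._setup(6)
        with pytest.raises(InvalidParameterError):
            simulate_expression(
                labels, net, [("G0000", "G0001")],
                [(0, 1, "G0002", "G0003", 2.0)], 20, 1.0, 2.0, seed=0,
            )

    def test_interface_fold_effect_magnitude(self):
        """Mean interface/non-interface ligand ratio near the planted fold."""
        ratios = []
        for seed in range(20):
            g, labels, net = self._setup(seed)
            counts, _, ifc = simulate_expression(
                labels, net, [("G0000", "G0001")],
                [(0, 1, "G0000", "G0001", 4.0)], 20, 2.0, 2.0, seed=seed,
            )
            si, _ = ifc[0]
            senders = np.flatnonzero(labels == 0)
            off = np.setdiff1d(senders, si)
            if len(si) < 4 or len(off) < 4:
                continue
            lig = np.asarray(counts[0].todense()).ravel()
            ratios.append(lig[si].mean() / lig[off].mean())
        assert abs(np.mean(ratios) - 4.0) / 4.0 < 0.25


class TestSimulateCohort:
    def test_bookkeeping(self, small_cohort):
        assert len(small_cohort.samples) == 6
        groups = small_cohort.sample_sheet["group"].value_counts()
        assert groups["primary"] == 3 and groups["recurrent"] == 3
        ids = [s.sample_id for s in small_cohort.samples]
        assert len(set(ids)) == 6
        for s in small_cohort.samples:
            assert len(small_cohort.truth.labels[s.sample_id]) == s.n_spots

    def test_determinism(self):
        kwargs = dict(
            grid_rows=10, grid_cols=10, n_types=3, n_genes=20,
            n_marker_genes=2, lr_catalog=default_lr_catalog(2),
            planted_lr=[], seed=5,
        )
        a = simulate_cohort(SimulationConfig(**kwargs))
        b = simulate_cohort(SimulationConfig(**kwargs))
        for sa, sb in zip(a.samples, b.samples):
            assert (sa.counts != sb.counts).nnz == 0
            assert np.array_equal(sa.coords, sb.coords)
            pd.testing.assert_frame_equal(a.deconv[sa.sample_id], b.deconv[sb.sample_id])
        pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)

    def test_flatter_alpha_raises_entropy(self):
        """Recurrent arm (flatter Dirichlet) has higher mean spot Shannon."""
        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(
                grid_rows=10, grid_cols=10, n_types=4, n_genes=12,
                n_marker_genes=1, lr_catalog=default_lr_catalog(2),
                planted_proximity=[], planted_lr=[],
                dirichlet_alpha_primary=(0.4,) * 4,
                dirichlet_alpha_recurrent=(0.8,) * 4,
                seed=100 + seed,
            )
            b = simulate_cohort(cfg)
            means = {
                g: np.mean(
                    [
                        shannon_index(b.deconv[s]).mean()
                        for s in b.sample_sheet.loc[
                            b.sample_sheet.group == g, "sample_id"
                        ]
                    ]
                )
                for g in ("primary", "recurrent")
            }
            wins += means["recurrent"] > means["primary"]
        assert wins >= 18
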