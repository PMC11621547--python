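"""Distance matrices, contact maps, structural correlation, graph
features, and the structure-conditioned model's contracts."""

import numpy as np
import pytest

from rnagen.sequence_io import AlignedFamily
from rnagen.structure import (
    ContactMap,
    DistanceMatrix,
    GNNConfig,
    StructuredSequenceModel,
    align_distance_matrix_to_msa,
    build_graph_features,
    contact_map_cutoff,
    contact_map_knn,
    encode_rows,
    gnn_generate,
    gnn_log_probability,
    gnn_train,
    knn_neighbors,
    min_atom_distance_matrix,
    min_uncovered_distance,
    random_degree_matched_neighbors,
    rbf_expand,
    structural_correlation,
    symmetrized,
)


@pytest.fixture(scope="module")
def d3():
    D = np.array([[0, 5, 20], [5, 0, 8], [20, 8, 0]], float)
    return DistanceMatrix(D=D, labels=list("abc"), mask=np.ones(3, bool))


class TestDistanceMatrix:
    def test_shared_atom_distance_zero(self):
        a = np.array([[1.0, 2.0, 3.0], [9, 9, 9]])
        b = np.array([[1.0, 2.0, 3.0]])
        dm = min_atom_distance_matrix([a, b])
        assert dm.D[0, 1] == 0.0

    def test_three_four_five(self):
        dm = min_atom_distance_matrix([np.array([[0.0, 0, 0]]), np.array([[3.0, 4, 0]])])
        assert dm.D[0, 1] == 5.0

    def test_matches_brute_force_all_atom_loop(self, rng):
        coords = [rng.normal(0, 5, size=(rng.integers(2, 6), 3)) for _ in range(4)]
        dm = min_atom_distance_matrix(coords)
        for i in range(4):
            for j in range(4):
                expect = min(
                    np.linalg.norm(p - q) for p in coords[i] for q in coords[j]
                ) if i != j else 0.0
                assert abs(dm.D[i, j] - expect) < 1e-9

    def test_empty_residue_masked(self):
        dm = min_atom_distance_matrix(
            [np.array([[0.0, 0, 0]]), np.zeros((0, 3)), np.array([[1.0, 0, 0]])]
        )
        assert not dm.mask[1]
        assert np.isinf(dm.D[0, 1])
        assert dm.D[0, 2] == 1.0


class TestStructureLoading:
    PDB = (
        "CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1\n"
        "ATOM      1  P     G A   1       0.000   0.000   0.000  1.00  0.00           P\n"
        "ATOM      2  O5'   G A   1       1.000   0.000   0.000  1.00  0.00           O\n"
        "ATOM      3  H5'   G A   1       1.500   0.500   0.000  1.00  0.00           H\n"
        "ATOM      4  P     A A   2       3.000   4.000   0.000  1.00  0.00           P\n"
        "ATOM      5  P   PSU A   3       6.000   8.000   0.000  1.00  0.00           P\n"
        "ATOM      6  P     U A   4      10.000   8.000   0.000  1.00  0.00           P\n"
        "END\n"
    )

    def test_pdb_chain_with_modified_residue(self, tmp_path):
        from rnagen.structure import load_chain_residues

        p = tmp_path / "mini.pdb"
        p.write_text(self.PDB)
        labels, coords, seq = load_chain_residues(p, "A")
        assert seq == "GAUU"  # pseudouridine maps to parent U
        assert [len(c) for c in coords] == [2, 1, 1, 1]  # hydrogens dropped
        dm = min_atom_distance_matrix(coords, labels)
        assert abs(dm.D[1, 2] - 5.0) < 1e-9  # 3-4-5 between P atoms

    def test_missing_chain_errors(self, tmp_path):
        from rnagen.structure import load_chain_residues

        p = tmp_path / "mini.pdb"
        p.write_text(self.PDB)
        with pytest.raises(ValueError, match="chain"):
            load_chain_residues(p, "B")


class TestContactMaps:
    def test_cutoff_example(self, d3):
        cm = contact_map_cutoff(d3, 12)
        assert cm.M.tolist() == [[0, 1, 0], [1, 0, 1], [0, 1, 0]]

    def test_knn_full_when_k_is_n_minus_1(self, d3):
        cm = contact_map_knn(d3, 2)
        assert cm.M.sum() == 6

    def test_knn1_argmin_per_row(self, d3):
        cm = contact_map_knn(d3, 1)
        assert cm.M[0].tolist() == [0, 1, 0]
        assert cm.M[2].tolist() == [0, 1, 0]

    def test_knn_k_too_large(self, d3):
        with pytest.raises(ValueError):
            contact_map_knn(d3, 3)

    def test_knn_tie_breaks_by_lower_index(self):
        D = np.array([[0, 7, 7], [7, 0, 7], [7, 7, 0]], float)
        dm = DistanceMatrix(D=D, labels=list("abc"), mask=np.ones(3, bool))
        nbr = knn_neighbors(dm, 1)
        assert nbr[:, 0].tolist() == [1, 0, 0]

    def test_cutoff_monotone_in_d(self, small_sample):
        dm = small_sample.distance
        a = contact_map_cutoff(dm, 8).support
        b = contact_map_cutoff(dm, 14).support
        assert (a <= b).all()

    def test_knn_monotone_in_k(self, small_sample):
        dm = small_sample.distance
        a = contact_map_knn(dm, 3).support
        b = contact_map_knn(dm, 6).support
        assert (a <= b).all()

    def test_masked_rows_empty(self, d3):
        dm = DistanceMatrix(D=d3.D.copy(), labels=d3.labels,
                            mask=np.array([True, False, True]))
        dm.D[1, :] = dm.D[:, 1] = np.inf
        dm.D[1, 1] = 0
        cm = contact_map_knn(dm, 1)
        assert cm.M[1].sum() == 0
        assert cm.M[:, 1].sum() == 0


class TestCorrelation:
    def test_self_correlation_one(self, d3):
        cm = contact_map_cutoff(d3, 12)
        assert structural_correlation(cm, cm) == 1.0

    def test_disjoint_zero(self):
        a = ContactMap(np.array([[0, 1], [1, 0]]), "cutoff", 1)
        b = ContactMap(np.array([[0, 0], [0, 0]]), "cutoff", 1)
        c = ContactMap(np.eye(2, dtype=int), "cutoff", 1)
        assert structural_correlation(a, c) == 0.0
        assert np.isnan(structural_correlation(a, b))

    def test_direct_formula(self):
        A = np.zeros((4, 4), int)
        B = np.zeros((4, 4), int)
        A[0, 1] = A[1, 0] = 1          # |A| = 2
        B[0, 1] = B[1, 0] = B[2, 3] = B[3, 2] = 1  # |B| = 4, overlap 2
        corr = structural_correlation(ContactMap(A, "c", 1), ContactMap(B, "c", 1))
        assert abs(corr - 2 / np.sqrt(8)) < 1e-12

    def test_symmetric(self, small_sample):
        a = contact_map_cutoff(small_sample.distance, 10)
        b = symmetrized(contact_map_knn(small_sample.distance, 4))
        assert structural_correlation(a, b) == structural_correlation(b, a)


class TestCoverage:
    def test_full_coverage_inf(self, d3):
        assert min_uncovered_distance(d3, 2) == np.inf

    def test_uncovered_pair(self, d3):
        assert min_uncovered_distance(d3, 1) == 20.0

    def test_monotone_in_k(self, small_sample):
        dm = small_sample.distance
        vals = [min_uncovered_distance(dm, k) for k in (2, 4, 8, 16)]
        assert vals == sorted(vals)


class TestMatrixAlignment:
    def _toy(self):
        fam = AlignedFamily(rows=[("ec", "AC-GU-"), ("other", "ACAGUA")])
        coords = [np.array([[0.0, 0, 0]]), np.array([[3.0, 0, 0]]),
                  np.array([[3.0, 4, 0]]), np.array([[0.0, 4, 0]])]
        dm = min_atom_distance_matrix(coords)
        return fam, dm

    def test_identity_when_no_gaps(self):
        fam, dm = self._toy()
        out, _ = align_distance_matrix_to_msa(dm, "ACGU", "ACGU", fam, "ec")
        assert np.allclose(out.D, dm.D)

    def test_unresolved_residue_gets_sentinel(self):
        fam, dm = self._toy()
        dm3 = min_atom_distance_matrix(
            [np.array([[0.0, 0, 0]]), np.array([[3.0, 4, 0]]), np.array([[0.0, 4, 0]])]
        )
        out, _ = align_distance_matrix_to_msa(dm3, "AGU", "ACGU", fam, "ec")
        assert out.D.shape == (4, 4)
        assert not out.mask[1]
        assert np.isinf(out.D[0, 1])

    def test_distances_survive_round_trip(self):
        fam, dm = self._toy()
        out, full_to_proj = align_distance_matrix_to_msa(dm, "ACGU", "ACGU", fam, "ec")
        for i in range(4):
            for j in range(4):
                pi, pj = full_to_proj[i], full_to_proj[j]
                assert abs(out.D[pi, pj] - dm.D[i, j]) < 1e-12


class TestGraphFeatures:
    def test_each_node_k_edges(self, small_sample):
        cfg = GNNConfig(k=5, hidden_dim=16)
        g = build_graph_features(small_sample.distance, cfg)
        assert g.neighbor_idx.shape == (small_sample.spec.length, 5)
        assert g.valid.all()

    def test_rbf_peaks_at_center(self):
        cfg = GNNConfig()
        centers = np.linspace(cfg.rbf_min, cfg.rbf_max, cfg.rbf_count)
        act = rbf_expand(np.array([centers[3]]), cfg)
        assert act[0].argmax() == 3
        assert abs(act[0, 3] - 1.0) < 1e-12

    def test_edge_feature_width(self, small_sample):
        cfg = GNNConfig(k=4, relpos_features=16, rbf_count=16)
        g = build_graph_features(small_sample.distance, cfg)
        assert g.edge_feat.shape[-1] == 16 + 16


def _tiny_gnn_setup(sample, k=4, hidden=24, seed=0):
    cfg = GNNConfig(k=k, hidden_dim=hidden, n_encoder_layers=1,
                    n_decoder_layers=2, dropout=0.1)
    g = build_graph_features(sample.distance, cfg)
    return cfg, g


class TestStructuredModel:
    def test_memorization(self, small_sample):
        # zero-entropy corpus: 80 copies of one aligned row
        cfg, g = _tiny_gnn_setup(small_sample)
        rows = encode_rows(small_sample.family)[:1]
        rows = np.repeat(rows, 80, axis=0)
        model = StructuredSequenceModel(g, cfg, rng_seed=0)
        model, rep = gnn_train(model, rows, rows[:8], max_iters=250,
                               batch_size=8, lr=3e-3, eval_interval=50,
                               early_stop_patience=10, rng_seed=0)
        assert rep.best_val_perplexity < 1.2

    def test_log_probability_finite_and_reproducible(self, small_sample):
        cfg, g = _tiny_gnn_setup(small_sample)
        model = StructuredSequenceModel(g, cfg, rng_seed=1)
        row = encode_rows(small_sample.family)[0]
        a = gnn_log_probability(model, row)
        b = gnn_log_probability(model, row)
        assert np.isfinite(a) and a == b

    def test_generation_seeded_and_reproducible(self, small_sample):
        cfg, g = _tiny_gnn_setup(small_sample)
        model = StructuredSequenceModel(g, cfg, rng_seed=1)
        seed_cols = encode_rows(small_sample.family)[0][:30]
        a = gnn_generate(model, seed_cols, n_sequences=4, temperature=0.7, rng_seed=3)
        b = gnn_generate(model, seed_cols, n_sequences=4, temperature=0.7, rng_seed=3)
        assert (a == b).all()
        assert (a[:, :30] == seed_cols).all()

    def test_same_seed_same_params(self, small_sample):
        cfg, g = _tiny_gnn_setup(small_sample)
        a = StructuredSequenceModel(g, cfg, rng_seed=4)
        b = StructuredSequenceModel(g, cfg, rng_seed=4)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_width_mismatch_errors(self, small_sample):
        cfg, g = _tiny_gnn_setup(small_sample)
        model = StructuredSequenceModel(g, cfg, rng_seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 17), dtype=np.int64))

    def test_structure_beats_no_edges_on_paired_family(self, small_sample):
        """With k=0 the model degrades to a per-column profile; the true
        contact graph carries base-pairing information and must win."""
        rows = encode_rows(small_sample.family)
        tr, va = rows[:400], rows[400:480]
        ppl = {}
        for k in (0, 4):
            cfg = GNNConfig(k=k, hidden_dim=24, n_encoder_layers=1,
                            n_decoder_layers=2, dropout=0.1)
            g = build_graph_features(small_sample.distance, cfg)
            m = StructuredSequenceModel(g, cfg, rng_seed=0)
            m, rep = gnn_train(m, tr, va, max_iters=300, batch_size=12, lr=2e-3,
                               eval_interval=75, early_stop_patience=4, rng_seed=0)
            ppl[k] = rep.best_val_perplexity
        assert ppl[4] < ppl[0]

    def test_random_degree_matched_control(self, small_sample):
        nbr = knn_neighbors(small_sample.distance, 5)
        rand = random_degree_matched_neighbors(nbr, 0)
        assert rand.shape == nbr.shape
        for i in range(rand.shape[0]):
            assert i not in rand[i]
            assert len(set(rand[i])) == rand.shape[1]
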