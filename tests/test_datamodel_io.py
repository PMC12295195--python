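import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spgrn import io
from spgrn.datamodel import ExpressionMatrix, SpotGeometry
from spgrn.io import FormatError


def _write_triplet(d, header_shape, entries, genes, barcodes):
    lines = ["%%MatrixMarket matrix coordinate integer general",
             f"{header_shape[0]} {header_shape[1]} {len(entries)}"]
    lines += [f"{i} {j} {v}" for i, j, v in entries]
    (d / "matrix.mtx").write_text("\n".join(lines) + "\n")
    (d / "genes.tsv").write_text("".join(f"{g}\n" for g in genes))
    (d / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))


class TestMatrixMarket:
    def test_triplet_transcription(self, tmp_path):
        _write_triplet(tmp_path, (3, 2), [(1, 1, 5), (3, 2, 2)],
                       ["A", "B", "C"], ["u1", "u2"])
        m = io.read_matrix_market(tmp_path)
        dense = m.counts.toarray()
        assert dense[0, 0] == 5 and dense[2, 1] == 2
        assert dense.sum() == 7
        assert list(m.genes) == ["A", "B", "C"]

    def test_empty_triplet_gives_zero_matrix(self, tmp_path):
        _write_triplet(tmp_path, (3, 2), [], ["A", "B", "C"], ["u1", "u2"])
        m = io.read_matrix_market(tmp_path)
        assert m.counts.nnz == 0 and m.counts.shape == (3, 2)

    def test_round_trip_identity(self, tmp_path, rng):
        counts = sp.random(30, 20, density=0.2, random_state=1, data_rvs=lambda n: rng.integers(1, 50, n))
        m = ExpressionMatrix(
            genes=np.array([f"g{i}" for i in range(30)], dtype=object),
            units=np.array([f"u{i}" for i in range(20)], dtype=object),
            counts=counts.tocsr().astype(np.int64),
        )
        io.write_matrix_market(m, tmp_path / "out")
        back = io.read_matrix_market(tmp_path / "out")
        assert (back.counts != m.counts).nnz == 0
        assert list(back.genes) == list(m.genes)

    def test_dimension_mismatch_raises(self, tmp_path):
        _write_triplet(tmp_path, (3, 2), [(1, 1, 5)], ["A", "B"], ["u1", "u2"])
        with pytest.raises(FormatError, match="matrix.mtx"):
            io.read_matrix_market(tmp_path)

    def test_non_integer_entries_raise(self, tmp_path):
        lines = ["%%MatrixMarket matrix coordinate real general", "2 2 1", "1 1 2.5"]
        (tmp_path / "matrix.mtx").write_text("\n".join(lines) + "\n")
        (tmp_path / "genes.tsv").write_text("A\nB\n")
        (tmp_path / "barcodes.tsv").write_text("u1\nu2\n")
        with pytest.raises(FormatError, match="non-integer"):
            io.read_matrix_market(tmp_path)


class TestSpotPositions:
    def _write(self, path, rows, header=True):
        lines = ["barcode,in_tissue,array_row,array_col,px_row,px_col"] if header else []
        lines += [",".join(map(str, r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")

    def test_collinear_neighbors(self, tmp_path):
        p = tmp_path / "pos.csv"
        self._write(p, [("a", 1, 0, 0, 0, 0), ("b", 1, 0, 1, 0, 100), ("c", 1, 0, 2, 0, 200)])
        geom = io.read_spot_positions(p)
        deg = geom.degree()
        assert sorted(deg.tolist()) == [1, 1, 2]

    def test_hex_patch_center_has_six_neighbors(self, tmp_path):
        # brute-force construction of one hex ring around the origin
        angles = np.arange(6) * np.pi / 3
        rows = [("c", 1, 0, 0, 0.0, 0.0)] + [
            (f"r{i}", 1, 0, 0, 100 * np.sin(a), 100 * np.cos(a))
            for i, a in enumerate(angles)
        ]
        p = tmp_path / "pos.csv"
        self._write(p, rows)
        geom = io.read_spot_positions(p)
        center = int(np.flatnonzero(geom.spot_ids == "c")[0])
        assert geom.degree()[center] == 6

    def test_single_spot_empty_adjacency(self, tmp_path):
        p = tmp_path / "pos.csv"
        self._write(p, [("a", 1, 0, 0, 0, 0)])
        geom = io.read_spot_positions(p)
        assert geom.neighbors.nnz == 0

    def test_duplicate_barcode_raises(self, tmp_path):
        p = tmp_path / "pos.csv"
        self._write(p, [("a", 1, 0, 0, 0, 0), ("a", 1, 0, 1, 0, 100)])
        with pytest.raises(FormatError, match="duplicate"):
            io.read_spot_positions(p)

    def test_square_grid_four_neighbors(self, tmp_path):
        rows = [(f"s{i}{j}", 1, i, j, 100 * i, 100 * j) for i in range(3) for j in range(3)]
        p = tmp_path / "pos.csv"
        self._write(p, rows)
        geom = io.read_spot_positions(p)
        center = int(np.flatnonzero(geom.spot_ids == "s11")[0])
        assert geom.degree()[center] == 4


class TestPriorTables:
    def test_duplicate_lr_row_deduplicated(self, tmp_path):
        lr = tmp_path / "lr.tsv"
        lr.write_text("ligand\treceptor\nLIF\tIL6ST\nLIF\tIL6ST\n")
        tt = tmp_path / "tt.tsv"
        tt.write_text("tf\ttarget\nJUN\tICAM1\n")
        lrdb, priors = io.read_table_priors(lr, tt)
        assert len(lrdb) == 1

    def test_missing_column_raises_with_name(self, tmp_path):
        lr = tmp_path / "lr.tsv"
        lr.write_text("ligand\tsomething\nLIF\tIL6ST\n")
        tt = tmp_path / "tt.tsv"
        tt.write_text("tf\ttarget\nJUN\tICAM1\n")
        with pytest.raises(FormatError, match="receptor"):
            io.read_table_priors(lr, tt)

    def test_five_row_exact_transcription(self, tmp_path):
        rows = [("L1", "R1"), ("L2", "R2"), ("L3", "R3"), ("L4", "R4"), ("L5", "R5")]
        lr = tmp_path / "lr.tsv"
        lr.write_text("ligand\treceptor\n" + "".join(f"{a}\t{b}\n" for a, b in rows))
        tt = tmp_path / "tt.tsv"
        tt.write_text("tf\ttarget\nT1\tG1\n")
        lrdb, _ = io.read_table_priors(lr, tt)
        assert lrdb.pair_tuples() == rows

    def test_absent_receptor_tf_is_none(self, tmp_path):
        lr = tmp_path / "lr.tsv"
        lr.write_text("ligand\treceptor\nL\tR\n")
        tt = tmp_path / "tt.tsv"
        tt.write_text("tf\ttarget\nT\tG\n")
        _, priors = io.read_table_priors(lr, tt, tmp_path / "nope.tsv")
        assert priors.receptor_tf is None

    def test_symbols_whitespace_trimmed(self, tmp_path):
        lr = tmp_path / "lr.tsv"
        lr.write_text("ligand\treceptor\n LIF \tIL6ST\n")
        tt = tmp_path / "tt.tsv"
        tt.write_text("tf\ttarget\nT\tG\n")
        lrdb, _ = io.read_table_priors(lr, tt)
        assert lrdb.pair_tuples() == [("LIF", "IL6ST")]


class TestNetworkExport:
    def _one_chain_network(self):
        import pandas as pd

        from spgrn.network import CHAIN_COLUMNS, LayeredNetwork

        chain = {
            "ligand": "L", "receptor": "R", "tf": "T", "target": "G",
            "sender": "fibroblast", "receiver": "malignant",
            "lr_score": 1.0, "lr_p_adj": 0.01, "rt_rho": 0.5, "tt_rho": 0.6,
            "in_N1": True, "in_N2": False, "in_N3": False, "in_N4": False,
        }
        return LayeredNetwork(chains=pd.DataFrame([chain], columns=CHAIN_COLUMNS))

    def test_one_chain_gives_three_edges_in_n1(self, tmp_path):
        net = self._one_chain_network()
        files = io.write_network(net, tmp_path / "net")
        edges = io.read_network_edges(files[0])
        assert len(edges) == 3
        assert set(edges["edge_type"]) == {"LR", "RT", "TT"}
        assert edges["in_N1"].all() and not edges["in_N4"].any()

    def test_empty_layer_round_trip(self, tmp_path):
        net = self._one_chain_network()
        files = io.write_network(net, tmp_path / "net")
        edges = io.read_network_edges(files[0])
        assert not edges["in_N4"].any()  # N4 GraphML exists but holds no edges
        import networkx as nx

        g4 = nx.read_graphml(tmp_path / "net_N4.graphml")
        assert g4.number_of_edges() == 0

    def test_round_trip_edge_set_equality(self, tmp_path):
        from spgrn import pipeline, simulate

        cfg = pipeline.RunConfig(seed=2, sim=simulate.compact_config(seed=2),
                                 n_perm=149, cells_per_type=100)
        res = pipeline.run_all(cfg)
        files = io.write_network(res.net, tmp_path / "net")
        back = io.read_network_edges(files[0])
        orig = res.net.edge_table()
        key = ["source", "target", "edge_type"]
        assert set(map(tuple, back[key].itertuples(index=False))) == set(
            map(tuple, orig[key].itertuples(index=False))
        )
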