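import numpy as np
import pytest
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from spgrn import preprocess
from spgrn.datamodel import ExpressionMatrix
from spgrn.preprocess import EmptyResultError, QCThresholds


def _matrix(counts, genes=None, units=None):
    counts = np.asarray(counts)
    g, u = counts.shape
    return ExpressionMatrix(
        genes=np.array(genes or [f"g{i}" for i in range(g)], dtype=object),
        units=np.array(units or [f"u{i}" for i in range(u)], dtype=object),
        counts=sp.csr_matrix(counts),
    )


def _cell_qc_oracle(counts, mito_rows, t):
    """Rule-by-rule reference implementation of the cell filter."""
    keep = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        total = col.sum()
        mito = col[mito_rows].sum() if len(mito_rows) else 0
        detected = (col > 0).sum()
        ok = (
            (mito / total if total else 0) <= t.mito_max_frac
            and t.umi_min <= total <= t.umi_max
            and detected >= t.genes_min_per_cell
        )
        keep.append(ok)
    return np.array(keep)


class TestFilterCells:
    def _toy(self, rng):
        """Cells crossing every threshold: mito fracs 0/.1/.25 x totals
        150/500/70000, detected genes controlled via spread."""
        n_genes = 300
        cols = []
        for mito_frac in (0.0, 0.1, 0.25):
            for total in (150, 500, 70000):
                col = np.zeros(n_genes, dtype=int)
                mito_counts = int(round(total * mito_frac))
                col[0] = mito_counts
                rest = total - mito_counts
                body = np.minimum(rng.multinomial(rest, np.ones(250) / 250), rest)
                col[1:251] = body
                cols.append(col)
        return np.column_stack(cols)

    def test_matches_exhaustive_oracle(self, rng):
        counts = self._toy(rng)
        m = _matrix(counts, genes=["MT-1"] + [f"g{i}" for i in range(1, 300)])
        t = QCThresholds()
        kept = preprocess.filter_cells(m, thresholds=t)
        expected = _cell_qc_oracle(counts, [0], t)
        assert list(kept.units) == list(m.units[expected])

    def test_high_mito_cell_removed(self):
        counts = np.zeros((300, 2), dtype=int)
        counts[0, 0] = 150          # 150 / 600 = 25% mito -> removed
        counts[1:226, 0] = 2        # 450 body counts, 226 genes detected
        counts[1:226, 1] = 2
        m = _matrix(counts, genes=["MT-1"] + [f"g{i}" for i in range(1, 300)])
        kept = preprocess.filter_cells(m)
        assert list(kept.units) == ["u1"]

    def test_all_pass_identity_and_idempotence(self, rng):
        counts = rng.integers(1, 5, size=(300, 6))
        m = _matrix(counts)
        once = preprocess.filter_cells(m)
        twice = preprocess.filter_cells(once)
        assert list(once.units) == list(m.units)
        assert list(twice.units) == list(once.units)

    def test_all_removed_raises(self):
        m = _matrix(np.ones((10, 3), dtype=int))  # 10 counts/cell << umi_min
        with pytest.raises(EmptyResultError):
            preprocess.filter_cells(m)


class TestFilterSpots:
    def test_gene_count_rules(self):
        """Gene seen in 3 spots totaling 9 is dropped; totaling 10 kept."""
        n_genes, n_spots = 250, 4
        counts = np.ones((n_genes, n_spots), dtype=int)  # all spots detect 250 genes
        counts[0] = [4, 4, 1, 0]   # 3 spots, total 9 -> dropped
        counts[1] = [4, 4, 2, 0]   # 3 spots, total 10 -> kept
        counts[2] = [5, 5, 0, 0]   # 2 spots -> dropped
        m = _matrix(counts)
        kept = preprocess.filter_spots(m)
        assert "g0" not in kept.genes and "g2" not in kept.genes
        assert "g1" in kept.genes

    def test_spot_with_199_genes_removed(self):
        counts = np.zeros((250, 5), dtype=int)
        counts[:199, 0] = 5          # 199 detected genes -> spot dropped
        counts[:, 1:] = 5            # four clean spots keep the gene axis alive
        m = _matrix(counts)
        kept = preprocess.filter_spots(m)
        assert "u0" not in kept.units and len(kept.units) == 4

    def test_dense_fixture_identity_and_idempotence(self, rng):
        counts = rng.integers(2, 9, size=(250, 5))  # every gene totals >= 10
        m = _matrix(counts)
        once = preprocess.filter_spots(m)
        twice = preprocess.filter_spots(once)
        assert once.counts.shape == m.counts.shape
        assert twice.counts.shape == once.counts.shape


class TestNormalize:
    def test_closed_form(self):
        m = _matrix([[1], [0]])
        out = preprocess.normalize_log1p(m, scale=1e4)
        assert out.normalized[0, 0] == pytest.approx(np.log(10001))
        assert out.normalized[1, 0] == 0.0

    def test_equal_columns_identical(self):
        m = _matrix(np.tile([[3], [5], [2]], (1, 4)))
        out = preprocess.normalize_log1p(m)
        assert np.allclose(out.normalized, out.normalized[:, :1])

    def test_matches_scalar_loop_oracle(self, rng):
        counts = rng.integers(0, 30, size=(50, 40))
        counts[0] += 1  # no zero column
        m = _matrix(counts)
        out = preprocess.normalize_log1p(m, scale=1e4)
        totals = counts.sum(axis=0)
        for g in range(50):
            for u in range(40):
                expected = np.log1p(1e4 * counts[g, u] / totals[u])
                assert abs(out.normalized[g, u] - expected) < 1e-12


class TestModuleScore:
    def test_single_gene_bins_cancel(self, random_norm_matrix):
        # n_bins == n_genes forces each control draw to be the gene itself
        m = random_norm_matrix
        score = preprocess.module_score(m, [m.genes[3], m.genes[17]], n_bins=m.n_genes, seed=0)
        assert np.allclose(score, 0.0)

    def test_constructed_shift_recovered(self, rng):
        """Eight expression strata of six genes each; one gene per stratum
        carries a +1 offset. With n_bins matching the strata, controls come
        from the same stratum, so the score recovers the offset."""
        n_bins, per_bin, n_units = 8, 6, 30
        vals = np.zeros((n_bins * per_bin, n_units))
        for b in range(n_bins):
            rows = slice(b * per_bin, (b + 1) * per_bin)
            vals[rows] = 10.0 * b + rng.normal(scale=0.01, size=(per_bin, n_units))
        gene_set = [f"g{b * per_bin}" for b in range(n_bins)]  # first gene of each stratum
        set_rows = [b * per_bin for b in range(n_bins)]
        vals[set_rows] += 1.0
        m = _matrix(np.ones_like(vals, dtype=int))
        m.normalized = vals
        score = preprocess.module_score(m, gene_set, n_bins=n_bins, n_ctrl=200, seed=1)
        assert np.all(np.abs(score - 1.0) < 0.25)

    def test_seed_determinism_and_unit_order_invariance(self, random_norm_matrix):
        m = random_norm_matrix
        s1 = preprocess.module_score(m, list(m.genes[:5]), seed=3, n_bins=10)
        s2 = preprocess.module_score(m, list(m.genes[:5]), seed=3, n_bins=10)
        assert np.array_equal(s1, s2)
        perm = np.random.default_rng(1).permutation(m.n_units)
        m_perm = m.subset_units(perm)
        s3 = preprocess.module_score(m_perm, list(m.genes[:5]), seed=3, n_bins=10)
        assert np.allclose(s1[perm], s3)

    def test_missing_gene_listed(self, random_norm_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            preprocess.module_score(random_norm_matrix, ["NOPE"], n_bins=10)


class TestCellTypeWeights:
    def test_single_type_invalid(self, random_norm_matrix):
        with pytest.raises(ValueError):
            preprocess.celltype_weights(random_norm_matrix, {"a": ["g001"]})

    def test_symmetric_swap(self, rng):
        m = _matrix(rng.integers(1, 5, size=(40, 20)))
        base = rng.normal(size=(40, 20))
        m.normalized = base.copy()
        m.normalized[0, :10] += 3  # gene 0 marks first half
        m.normalized[1, 10:] += 3  # gene 1 marks second half
        w = preprocess.celltype_weights(m, {"A": ["g0"], "B": ["g1"]}, n_bins=5, seed=0)
        w_swapped = preprocess.celltype_weights(m, {"A": ["g1"], "B": ["g0"]}, n_bins=5, seed=0)
        assert list(w.labels[:10]) == ["A"] * 10
        assert list(w_swapped.labels[:10]) == ["B"] * 10

    def test_pure_type_spots_recovered(self, small_tissue):
        (m, geom, w_true, truth), cfg = small_tissue
        mn = preprocess.normalize_log1p(preprocess.filter_spots(m))
        names = cfg.gene_names()
        marker_sets = {t: [names[i] for i in idx] for t, idx in cfg.marker_indices().items()}
        w = preprocess.celltype_weights(mn, marker_sets, seed=0)
        acc = (w.labels == truth.dominant_type).mean()
        assert acc >= 0.95


class TestWilcoxonDEG:
    def test_identical_groups_give_p_one(self, rng):
        counts = rng.integers(1, 30, size=(30, 12))
        half = np.column_stack([counts, counts])
        m = _matrix(half, units=[f"a{i}" for i in range(12)] + [f"b{i}" for i in range(12)])
        m = preprocess.normalize_log1p(m)
        deg = preprocess.wilcoxon_deg(m, [f"a{i}" for i in range(12)], [f"b{i}" for i in range(12)])
        assert np.allclose(deg["p"], 1.0)

    def test_bh_textbook_example(self):
        _, p_adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(p_adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=60)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        # textbook step-up computation
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        assert np.allclose(p_adj, adj, atol=1e-12)

    def test_overlapping_groups_rejected(self, rng):
        m = _matrix(rng.integers(1, 9, size=(20, 10)))
        m = preprocess.normalize_log1p(m)
        with pytest.raises(ValueError, match="overlap"):
            preprocess.wilcoxon_deg(m, ["u0", "u1", "u2"], ["u2", "u3", "u4"])

    def test_planted_fourfold_gene_detected(self, rng):
        """A 4-fold gene at n=100 vs 100 under NB dispersion 0.5 is found
        at adjusted p < 0.05 in nearly every replicate."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            k = 2.0  # 1/dispersion
            base = r.negative_binomial(k, k / (k + 20.0), size=(40, 200))
            base[0, :100] = r.negative_binomial(k, k / (k + 80.0), size=100)
            m = _matrix(base + (base.sum(axis=0) == 0))
            m = preprocess.normalize_log1p(m)
            deg = preprocess.wilcoxon_deg(m, m.units[:100], m.units[100:])
            hits += bool(deg.loc[deg["gene"] == "g0", "significant"].iloc[0])
        assert hits >= 9

    def test_null_type_one_error_calibrated(self, rng):
        G = 300
        counts = rng.integers(1, 40, size=(G, 60))
        m = _matrix(counts)
        m = preprocess.normalize_log1p(m)
        deg = preprocess.wilcoxon_deg(m, m.units[:30], m.units[30:])
        frac = (deg["p"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / G)
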