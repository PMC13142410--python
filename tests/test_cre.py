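"""Gene domains, summit/window pipeline and element statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from cocotag import cre, sim
from tests.conftest import brute_force_overlap_counts


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def _summits(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "score"])


class TestGeneDomains:
    def test_middle_gene_bounded_by_neighbors(self):
        genes = _genes([("chr1", 100, 200, "A"), ("chr1", 500, 600, "B"),
                        ("chr1", 900, 1000, "C")])
        dom, dropped = cre.gene_domains(genes)
        d = dom.set_index("gene")
        assert (d.loc["B", "domain_start"], d.loc["B", "domain_end"]) == (200, 900)
        assert dropped == 0

    def test_chromosome_edge_uses_min_max_coordinate(self):
        genes = _genes([("chr1", 100, 200, "A"), ("chr1", 500, 600, "B")])
        d = cre.gene_domains(genes)[0].set_index("gene")
        assert d.loc["A", "domain_start"] == 100   # min annotated coordinate
        assert d.loc["B", "domain_end"] == 600     # max annotated coordinate

    def test_overlapping_neighbor_skipped(self):
        # B overlaps A but not C; C's upstream boundary is B's end
        genes = _genes([("chr1", 100, 300, "A"), ("chr1", 250, 600, "B"),
                        ("chr1", 900, 1000, "C")])
        d = cre.gene_domains(genes)[0].set_index("gene")
        assert d.loc["C", "domain_start"] == 600

    def test_domain_contains_gene(self, rng):
        starts = np.sort(rng.integers(0, 100_000, 40))
        genes = _genes([
            ("chr1", int(s), int(s + rng.integers(100, 3000)), f"g{i}")
            for i, s in enumerate(starts)
        ])
        dom, _ = cre.gene_domains(genes)
        assert (dom["domain_start"] <= dom["gene_start"]).all()
        assert (dom["domain_end"] >= dom["gene_end"]).all()

    def test_matches_brute_force_scan(self, rng):
        starts = rng.integers(0, 50_000, 25)
        genes = _genes([
            ("chr1", int(s), int(s + rng.integers(100, 5000)), f"g{i}")
            for i, s in enumerate(starts)
        ])
        dom, _ = cre.gene_domains(genes)
        d = dom.set_index("gene")
        lo, hi = genes["start"].min(), genes["end"].max()
        for row in genes.itertuples(index=False):
            ups = [g.end for g in genes.itertuples(index=False) if g.end <= row.start]
            dns = [g.start for g in genes.itertuples(index=False) if g.start >= row.end]
            expected_start = max(ups) if ups else lo
            expected_end = min(dns) if dns else hi
            if expected_start >= expected_end:
                assert row.gene not in d.index
            else:
                assert d.loc[row.gene, "domain_start"] == expected_start
                assert d.loc[row.gene, "domain_end"] == expected_end

    def test_collapse_transcripts_union_span(self):
        tx = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [100, 150, 400],
                "end": [300, 500, 450],
                "gene": ["A", "A", "A"],
            }
        )
        out = cre.collapse_transcripts(tx)
        assert out.values.tolist() == [["chr1", 100, 500, "A"]]


def greedy_merge_oracle(positions, scores, collapse_bp=100):
    """Independent restatement of the greedy sweep for small instances."""
    order = np.argsort(positions, kind="stable")
    kept = []
    for idx in order:
        p, s = positions[idx], scores[idx]
        if kept and p - kept[-1][0] <= collapse_bp:
            if s > kept[-1][1]:
                kept[-1] = (p, s)
        else:
            kept.append((p, s))
    return kept


class TestMergeSummits:
    def test_chain_keeps_highest(self):
        s = _summits([("chr1", 100, 5.0), ("chr1", 180, 9.0), ("chr1", 270, 3.0)])
        out = cre.merge_summits(s)
        assert out[["start", "score"]].values.tolist() == [[180, 9.0]]

    def test_beyond_window_both_kept(self):
        s = _summits([("chr1", 100, 5.0), ("chr1", 251, 9.0)])
        assert len(cre.merge_summits(s)) == 2

    def test_single_summit_identity(self):
        s = _summits([("chr1", 42, 1.0)])
        assert cre.merge_summits(s)["start"].tolist() == [42]

    def test_chromosomes_independent(self):
        s = _summits([("chr1", 100, 5.0), ("chr2", 150, 9.0)])
        assert len(cre.merge_summits(s)) == 2

    @settings(max_examples=300, deadline=None)
    @given(
        positions=st.lists(st.integers(0, 600), min_size=1, max_size=6),
        scores=st.lists(st.integers(1, 100), min_size=6, max_size=6),
    )
    def test_matches_greedy_oracle(self, positions, scores):
        n = len(positions)
        s = _summits([("chr1", p, float(sc)) for p, sc in zip(positions, scores[:n])])
        out = cre.merge_summits(s)
        expected = greedy_merge_oracle(
            np.array(positions), np.array(scores[:n], dtype=float)
        )
        assert out[["start", "score"]].values.tolist() == [list(map(float, e)) for e in expected]

    @settings(max_examples=200, deadline=None)
    @given(positions=st.lists(st.integers(0, 1000), min_size=1, max_size=8))
    def test_retained_gaps_exceed_window(self, positions):
        s = _summits([("chr1", p, 1.0 + i) for i, p in enumerate(positions)])
        out = cre.merge_summits(s)
        gaps = np.diff(np.sort(out["start"].to_numpy()))
        assert (gaps > 100).all() if gaps.size else True


class TestSummitWindows:
    def test_centered_window(self):
        w = cre.summit_windows(_summits([("chr1", 500, 1.0)]).assign(end=501))
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (400, 600)

    def test_edge_clipping(self):
        w = cre.summit_windows(
            _summits([("chr1", 50, 1.0)]), chrom_sizes={"chr1": 130}
        )
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (0, 130)

    def test_widths_bounded(self, rng):
        s = _summits([("chr1", int(p), 1.0) for p in rng.integers(0, 5000, 50)])
        w = cre.summit_windows(s, chrom_sizes={"chr1": 5000})
        assert ((w["end"] - w["start"]) <= 200).all()


class TestCrossLineageMerge:
    def test_identical_windows_collapse(self):
        w = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600]})
        out = cre.cross_lineage_merge([w, w.copy()], _summits([("chr1", 500, 9.0)]))
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (400, 600)

    def test_offset_windows_recentered_on_top_summit(self):
        w1 = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600]})
        w2 = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [700]})
        summits = _summits([("chr1", 500, 5.0), ("chr1", 600, 9.0)])
        out = cre.cross_lineage_merge([w1, w2], summits)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (500, 700)

    def test_disjoint_windows_pass_through(self):
        w1 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        w2 = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1200]})
        out = cre.cross_lineage_merge([w1, w2], _summits([("chr1", 100, 1.0)]))
        assert len(out) == 2


class TestQuantify:
    def _matrix(self, rng, n_win=20, n_frag=200):
        win = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_win) * 500,
                "end": np.arange(n_win) * 500 + 200,
                "id": [f"w{i}" for i in range(n_win)],
            }
        )
        frags = {}
        for key in (("A", "m1"), ("B", "m1")):
            start = rng.integers(0, n_win * 500, n_frag)
            frags[key] = pd.DataFrame(
                {"chrom": "chr1", "start": start, "end": start + rng.integers(50, 300, n_frag),
                 "cell": key[0]}
            )
        return win, frags

    def test_cpm_formula(self):
        win = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200], "id": ["w0"]})
        start = np.concatenate([np.full(10, 50), np.full(999_990, 100_000)])
        frags = {("A", "m"): pd.DataFrame(
            {"chrom": "chr1", "start": start, "end": start + 100, "cell": "A"}
        )}
        mat = cre.quantify(win, frags)
        assert mat.values.iloc[0, 0] == pytest.approx(10.0)

    def test_abutting_fragment_not_counted(self):
        win = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300], "id": ["w0"]})
        frags = {("A", "m"): pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 300], "end": [100, 400], "cell": "A"}
        )}
        mat = cre.quantify(win, frags)
        assert mat.values.iloc[0, 0] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        win, frags = self._matrix(rng)
        mat = cre.quantify(win, frags)
        for key, f in frags.items():
            oracle = brute_force_overlap_counts(win, f) * 1e6 / len(f)
            np.testing.assert_allclose(mat.values[key], oracle)

    def test_column_totals_conserved(self, rng):
        """CPM column sums equal 1e6 x (in-window fragment fraction), counted
        with multiplicity by the brute-force oracle."""
        win, frags = self._matrix(rng)
        mat = cre.quantify(win, frags)
        for key, f in frags.items():
            oracle_total = brute_force_overlap_counts(win, f).sum() * 1e6 / len(f)
            assert mat.values[key].sum() == pytest.approx(oracle_total)


class TestOutlierFilter:
    def _mat(self, sums):
        n = len(sums)
        win = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 300,
                            "end": np.arange(n) * 300 + 200,
                            "id": [f"w{i}" for i in range(n)]})
        values = pd.DataFrame({("A", "m"): np.asarray(sums, dtype=float)},
                              index=win["id"])
        values.columns = pd.MultiIndex.from_tuples(values.columns, names=["cluster", "mark"])
        return cre.ElementMatrix(windows=win, values=values)

    def test_hundred_distinct_rows_keep_ninety(self):
        mat = self._mat(np.arange(100))
        out = cre.outlier_filter(mat)
        assert len(out.values) == 90

    def test_all_tied_rows_all_retained(self):
        mat = self._mat(np.full(50, 7.0))
        assert len(cre.outlier_filter(mat).values) == 50

    def test_matches_percentile_oracle(self, rng):
        sums = rng.random(73)
        mat = self._mat(sums)
        out = cre.outlier_filter(mat)
        lo, hi = np.percentile(sums, [5, 95])
        expected = ((sums >= lo) & (sums <= hi)).sum()
        assert len(out.values) == expected


class TestClusterElements:
    def test_mark_block_norms_equalized(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            np.abs(rng.normal(size=(40, 4))),
            columns=pd.MultiIndex.from_tuples(
                [("A", "m1"), ("B", "m1"), ("A", "m2"), ("B", "m2")],
                names=["cluster", "mark"],
            ),
        )
        values[("A", "m2")] *= 10  # inflate one block
        X = cre._normalized_features(values)
        marks = values.columns.get_level_values("mark")
        n1 = np.linalg.norm(X[:, marks == "m1"])
        n2 = np.linalg.norm(X[:, marks == "m2"])
        assert n1 == pytest.approx(n2, rel=1e-9)

    def test_duplicated_row_same_label(self):
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(size=(60, 4))) + np.repeat(
            np.eye(2, 2).repeat(2, axis=1) * 5, 30, axis=0
        )
        base[1] = base[0]  # exact duplicate
        win = pd.DataFrame({"chrom": "chr1", "start": np.arange(60) * 300,
                            "end": np.arange(60) * 300 + 200,
                            "id": [f"w{i}" for i in range(60)]})
        values = pd.DataFrame(
            base,
            index=win["id"],
            columns=pd.MultiIndex.from_tuples(
                [("A", "m1"), ("B", "m1"), ("A", "m2"), ("B", "m2")],
                names=["cluster", "mark"],
            ),
        )
        mat = cre.ElementMatrix(windows=win, values=values)
        labels, _ = cre.cluster_elements(mat, n_pcs=4, k=10, resolution=0.5, seed=0)
        assert labels.iloc[0] == labels.iloc[1]

    def test_seeded_determinism(self, planted_matrix):
        l1, _ = cre.cluster_elements(planted_matrix, n_pcs=4, k=15, resolution=0.25, seed=0)
        l2, _ = cre.cluster_elements(planted_matrix, n_pcs=4, k=15, resolution=0.25, seed=0)
        pd.testing.assert_series_equal(l1, l2)


@pytest.fixture(scope="module")
def planted_pipeline():
    cfg = sim.SimConfig(seed=5)
    summits, frags, truth = sim.simulate_summits(cfg)
    window_sets = []
    for s in summits.values():
        window_sets.append(cre.summit_windows(cre.merge_summits(s), 200))
    final = cre.cross_lineage_merge(
        window_sets, pd.concat(summits.values(), ignore_index=True), 200
    )
    mat = cre.outlier_filter(cre.quantify(final, frags))
    centers = (mat.windows["start"] + mat.windows["end"]) // 2
    nearest = np.abs(
        centers.to_numpy()[:, None] - truth["pos"].to_numpy()[None, :]
    ).argmin(axis=1)
    true_cls = truth["cls"].to_numpy()[nearest]
    return cfg, truth, mat, true_cls


@pytest.fixture(scope="module")
def planted_matrix(planted_pipeline):
    return planted_pipeline[2]


class TestPlantedRecovery:
    def test_element_classes_recovered(self, planted_pipeline):
        """Full pipeline on well-separated planted classes: high ARI and the
        promoter class overlapping planted TSSs."""
        cfg, truth, mat, true_cls = planted_pipeline
        labels, _ = cre.cluster_elements(mat, n_pcs=16, k=30, resolution=0.25, seed=0)
        assert adjusted_rand_score(true_cls, labels.to_numpy()) >= 0.8
        tss = truth.loc[truth["cls"] == "promoter", ["chrom", "pos"]]
        pf = cre.promoter_fraction(mat.windows, labels, tss)
        prom_label = labels[true_cls == "promoter"].mode()[0]
        assert pf[prom_label] > 0.8

    def test_recluster_overwrites_only_selection(self, planted_pipeline):
        _, _, mat, _ = planted_pipeline
        labels, _ = cre.cluster_elements(mat, n_pcs=4, k=15, resolution=0.25, seed=0)
        refined = cre.recluster(mat, labels, selected=[0], resolution=0.5, seed=0)
        untouched = labels != 0
        assert (refined[untouched] == labels[untouched].astype(str)).all()
        assert refined[labels == 0].str.startswith("0.").all()

    def test_recluster_empty_selection_identity(self, planted_pipeline):
        _, _, mat, _ = planted_pipeline
        labels, _ = cre.cluster_elements(mat, n_pcs=4, k=15, resolution=0.25, seed=0)
        refined = cre.recluster(mat, labels, selected=[])
        assert (refined == labels.astype(str)).all()


class TestPromoterFraction:
    def test_all_inside_tss_windows(self):
        win = pd.DataFrame({"chrom": "chr1", "start": [900, 1100], "end": [1100, 1300],
                            "id": ["w0", "w1"]})
        labels = pd.Series([0, 0], index=win["id"])
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]})
        pf = cre.promoter_fraction(win, labels, tss)
        assert pf[0] == 1.0

    def test_disjoint_chromosomes_zero(self):
        win = pd.DataFrame({"chrom": "chr2", "start": [0], "end": [200], "id": ["w0"]})
        labels = pd.Series([0], index=win["id"])
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        assert cre.promoter_fraction(win, labels, tss)[0] == 0.0

    def test_matches_brute_force(self, rng):
        win = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 50_000, 40)})
        win["end"] = win["start"] + 200
        win["id"] = [f"w{i}" for i in range(40)]
        labels = pd.Series(rng.integers(0, 3, 40), index=win["id"])
        tss = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 50_000, 6)})
        prom = pd.DataFrame({"chrom": "chr1", "start": np.maximum(tss["pos"] - 2000, 0),
                             "end": tss["pos"] + 2000})
        hits = brute_force_overlap_counts(win[["chrom", "start", "end"]], prom) > 0
        pf = cre.promoter_fraction(win, labels, tss)
        for cls in (0, 1, 2):
            sel = labels.to_numpy() == cls
            if sel.any():
                assert pf[cls] == pytest.approx(hits[sel].mean())


class TestDomainEnrichment:
    def _setup(self):
        win = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(20) * 1000,
            "end": np.arange(20) * 1000 + 200,
            "id": [f"w{i}" for i in range(20)],
        })
        labels = pd.Series(np.repeat([0, 1], 10), index=win["id"])
        dom_a = pd.DataFrame({"chrom": "chr1", "domain_start": [0], "domain_end": [10_000],
                              "gene": ["gA"]})
        dom_b = pd.DataFrame({"chrom": "chr1", "domain_start": [10_000], "domain_end": [20_000],
                              "gene": ["gB"]})
        return win, labels, {"grpA": dom_a, "grpB": dom_b}

    def test_exclusive_classes_signed_enrichment(self):
        win, labels, groups = self._setup()
        enrich, weights = cre.domain_enrichment(win, labels, groups)
        assert enrich.loc[0, "grpA"] > 0 > enrich.loc[0, "grpB"]
        assert enrich.loc[1, "grpB"] > 0 > enrich.loc[1, "grpA"]
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-12)

    def test_arithmetic_matches_hand_computation(self, rng):
        win, labels, groups = self._setup()
        enrich, weights = cre.domain_enrichment(win, labels, groups)
        # recompute by hand with the overlap oracle
        for cls in (0, 1):
            sel = labels.to_numpy() == cls
            for g, dom in groups.items():
                d = dom.rename(columns={"domain_start": "start", "domain_end": "end"})
                hits = brute_force_overlap_counts(win[["chrom", "start", "end"]], d) > 0
                obs = hits[sel].sum()
                f = hits.mean()
                exp = sel.sum() * f
                assert enrich.loc[cls, g] == pytest.approx(
                    np.log2((obs + 0.5) / (exp + 0.5))
                )
        ew = np.exp2(0)  # softmax checked via direct formula
        e = enrich.to_numpy()
        soft = np.exp(e - e.max(axis=1, keepdims=True))
        soft = soft / soft.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(weights.to_numpy(), soft, atol=1e-12)

    def test_overlapping_gene_groups_rejected(self):
        win, labels, groups = self._setup()
        with pytest.raises(ValueError, match="more than one"):
            cre.domain_enrichment(
                win, labels, groups,
                group_genes={"grpA": ["g1", "g2"], "grpB": ["g2"]},
            )

    def test_uniform_counts_zero_enrichment(self):
        """O == E: enrichment 0 everywhere would need identical overlap
        fractions; verified with a single all-covering group."""
        win, labels, _ = self._setup()
        dom = pd.DataFrame({"chrom": "chr1", "domain_start": [0], "domain_end": [100_000],
                            "gene": ["g"]})
        enrich, weights = cre.domain_enrichment(win, labels, {"all": dom})
        np.testing.assert_allclose(enrich.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(weights.to_numpy(), 1.0)


class TestCooccurrence:
    def test_haldane_log2_or_worked_example(self):
        presence = pd.DataFrame(
            {
                "A": [True] * 15 + [False] * 85,
                "B": [True] * 10 + [False] * 5 + [True] * 5 + [False] * 80,
            }
        )
        out = cre.cooccurrence(presence)
        expected = np.log2((10.5 * 80.5) / (5.5 * 5.5))
        assert out.loc[0, "log2_or"] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(4.805, abs=1e-3)

    def test_independent_table_null(self):
        # perfectly proportional 2x2: OR = 1, p = 1
        presence = pd.DataFrame(
            {
                "A": [True] * 20 + [False] * 20,
                "B": ([True] * 10 + [False] * 10) * 2,
            }
        )
        out = cre.cooccurrence(presence)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert 2 ** out.loc[0, "log2_or"] == pytest.approx(1.0, rel=0.1)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric probabilities
        <= the observed table's, for a small 12-gene table."""
        a, b, c, d = 5, 1, 2, 4  # n = 12
        presence = pd.DataFrame(
            {
                "A": [True] * (a + b) + [False] * (c + d),
                "B": [True] * a + [False] * b + [True] * c + [False] * d,
            }
        )
        out = cre.cooccurrence(presence)
        n, K, N = a + b + c + d, a + b, a + c
        probs = [hypergeom.pmf(k, n, K, N) for k in range(max(0, K + N - n), min(K, N) + 1)]
        p_obs = hypergeom.pmf(a, n, K, N)
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_log2_or_antisymmetric_under_only_cell_swap(self):
        t1 = pd.DataFrame({"A": [True] * 12 + [False] * 8,
                           "B": [True] * 6 + [False] * 6 + [True] * 6 + [False] * 2})
        t2 = pd.DataFrame({"A": t1["B"], "B": t1["A"]})
        o1 = cre.cooccurrence(t1).loc[0, "log2_or"]
        o2 = cre.cooccurrence(t2).loc[0, "log2_or"]
        assert o1 == pytest.approx(o2)  # swapping both labels: symmetric
        # swapping only_a/only_b inverts the off-diagonal -> OR unchanged
        # by construction; antisymmetry applies to the odds ratio itself:
        flipped = pd.DataFrame({"A": t1["A"], "B": ~t1["B"]})
        o3 = cre.cooccurrence(flipped).loc[0, "log2_or"]
        assert o3 == pytest.approx(-o1)

    def test_bh_adjustment_step_up(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])


class TestCooccurrenceNetwork:
    def test_backbone_keeps_significant_positive(self):
        cooc = pd.DataFrame(
            {
                "class_a": ["A", "A", "B"],
                "class_b": ["B", "C", "C"],
                "log2_or": [3.0, -2.0, 1.0],
                "p": [0.001, 0.001, 0.2],
                "fdr": [0.003, 0.003, 0.2],
                "significant": [True, True, False],
            }
        )
        edges = cre.cooccurrence_network(cooc)
        assert edges[["class_a", "class_b"]].values.tolist() == [["A", "B"]]


class TestDomainElementStats:
    def test_gene_element_counts_oracle(self, rng):
        win = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 30_000, 30)})
        win["end"] = win["start"] + 200
        win["id"] = [f"w{i}" for i in range(30)]
        labels = pd.Series(rng.integers(0, 2, 30), index=win["id"])
        domains = pd.DataFrame(
            {"chrom": "chr1", "domain_start": [0, 10_000, 20_000],
             "domain_end": [10_000, 20_000, 30_000], "gene": ["g1", "g2", "g3"]}
        )
        counts = cre.gene_element_counts(win, labels, domains, classes=[0, 1])
        for gi, g in enumerate(["g1", "g2", "g3"]):
            d = domains.iloc[[gi]].rename(
                columns={"domain_start": "start", "domain_end": "end"}
            )
            for cls in (0, 1):
                sub = win[labels.to_numpy() == cls].reset_index(drop=True)
                expected = (brute_force_overlap_counts(sub, d) > 0).sum()
                assert counts.loc[g, cls] == expected

    def test_peak_max_signal(self):
        values = pd.DataFrame(
            {("A", "m1"): [1.0, 5.0], ("B", "m1"): [4.0, 2.0], ("A", "m2"): [9.0, 0.0]},
            index=["w0", "w1"],
        )
        values.columns = pd.MultiIndex.from_tuples(values.columns, names=["cluster", "mark"])
        win = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 300],
                            "end": [200, 500], "id": ["w0", "w1"]})
        mat = cre.ElementMatrix(windows=win, values=values)
        out = cre.peak_max_signal(mat, "m1")
        assert out.tolist() == [4.0, 5.0]
        with pytest.raises(ValueError):
            cre.peak_max_signal(mat, "absent")

    def test_identical_groups_null_u(self):
        values = pd.Series(np.arange(8, dtype=float), index=[f"g{i}" for i in range(8)])
        groups = {"x": [f"g{i}" for i in range(8)], "y": [f"g{i}" for i in range(8)]}
        out = cre.group_compare(values, groups, [("x", "y")])
        assert out.loc[0, "U"] == 8 * 8 / 2
        assert out.loc[0, "p"] > 0.9

    def test_extreme_separation_exact_p(self):
        """Groups (1,2,3) vs (10,11,12): U = 0 and the exact two-sided
        rank-sum p equals 0.1 (2/20 orderings)."""
        values = pd.Series([1, 2, 3, 10, 11, 12], dtype=float,
                           index=list("abcdef"))
        groups = {"lo": list("abc"), "hi": list("def")}
        out = cre.group_compare(values, groups, [("lo", "hi")])
        assert out.loc[0, "U"] == 0.0
        assert out.loc[0, "p"] == pytest.approx(0.1)
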