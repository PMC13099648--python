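"""snRNA-seq QC, DE, APOE-high classification and the multilevel filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hippoexc.genes import (CONTRAST_KEYS, CountMatrix, classify_apoe_high,
                            find_markers, greedy_cluster_match, jaccard_similarity,
                            lognormalize, multilevel_filter, qc_filter,
                            standard_contrasts, wilcoxon_de)
from hippoexc.simulate import (PlantedPattern, SynthCountConfig,
                               candidate_group_lfcs, simulate_counts,
                               standard_planted_patterns)


def toy_counts(matrix):
    m = np.asarray(matrix)
    genes = [f"g{i}" for i in range(m.shape[0])]
    cells = [f"c{j}" for j in range(m.shape[1])]
    return CountMatrix(sp.csr_matrix(m), genes, cells)


class TestQcFilter:
    def meta(self, rows):
        return pd.DataFrame(rows, columns=["n_genes_detected", "n_umi",
                                           "mito_fraction"])

    def test_inclusive_bounds_retained(self):
        cm = toy_counts(np.ones((3, 1)))
        meta = self.meta([(2400, 4500, 0.001)])
        out, metaf = qc_filter(cm, meta)
        assert len(metaf) == 1

    def test_mito_strictly_less_than(self):
        cm = toy_counts(np.ones((3, 2)))
        meta = self.meta([(1000, 2000, 0.0025), (1000, 2000, 0.0024)])
        _, metaf = qc_filter(cm, meta)
        assert len(metaf) == 1
        assert metaf["mito_fraction"].iloc[0] == 0.0024

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(0)
        n = 10
        meta = self.meta([(int(rng.integers(100, 3000)),
                           int(rng.integers(300, 6000)),
                           float(rng.uniform(0, 0.005))) for _ in range(n)])
        cm = toy_counts(np.ones((4, n)))
        _, metaf = qc_filter(cm, meta)
        keep = [(200 <= g <= 2400) and (500 <= u <= 4500) and m < 0.0025
                for g, u, m in meta.itertuples(index=False)]
        assert len(metaf) == sum(keep)

    def test_all_removed_rejected(self):
        cm = toy_counts(np.ones((3, 1)))
        with pytest.raises(ValueError):
            qc_filter(cm, self.meta([(10, 10, 0.9)]))


class TestLognormalize:
    def test_formula(self):
        # one cell with total 10,000: count 100 -> ln(101)
        col = np.zeros((101, 1))
        col[0, 0] = 100
        col[1:, 0] = 99  # fill to total 10000: 100 + 100*99 = 10000
        cm = toy_counts(col)
        norm = lognormalize(cm)
        assert norm[0, 0] == pytest.approx(np.log(101.0))

    def test_zero_count_stays_zero(self):
        cm = toy_counts([[0, 5], [10, 5]])
        norm = lognormalize(cm)
        assert norm[0, 0] == 0.0

    def test_invariant_to_cell_scaling(self):
        cm1 = toy_counts([[1, 2], [3, 4]])
        cm2 = toy_counts([[7, 2], [21, 4]])  # first cell scaled by 7
        n1 = lognormalize(cm1).toarray()
        n2 = lognormalize(cm2).toarray()
        assert np.allclose(n1, n2)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            lognormalize(toy_counts([[0, 1], [0, 1]]))


class TestWilcoxonDe:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(5.0, size=(20, 200)).astype(float)
        cm = toy_counts(m)
        norm = lognormalize(cm)
        res = wilcoxon_de(norm, np.arange(100), np.arange(100, 200), cm.genes)
        t = res.table[res.table.tested]
        assert (t["p_raw"] > 0.001).all()
        assert t["log_fc"].abs().max() < 0.3

    def test_planted_effect_detected(self):
        planted = {"gene0000": PlantedPattern({("E4", 5): 1.0})}
        cfg = SynthCountConfig(n_genes=50, cells_per_group=200,
                               planted_genes=planted, gene_names=("gene0000",),
                               seed=2)
        cm, meta = simulate_counts(cfg)
        norm = lognormalize(cm)
        a = np.flatnonzero(((meta.genotype == "E4") & (meta.age_months == 5)).values)
        b = np.flatnonzero(((meta.genotype == "E3") & (meta.age_months == 5)).values)
        row = wilcoxon_de(norm, a, b, cm.genes).table.set_index("gene").loc["gene0000"]
        assert bool(row["tested"])
        assert row["p_raw"] < 0.001
        assert 0.4 < row["log_fc"] < 1.6

    def test_pct_gate_excludes_rare_gene(self):
        rng = np.random.default_rng(3)
        m = np.zeros((2, 200))
        m[0] = rng.poisson(5.0, 200) + 1  # keeps cells' totals nonzero
        m[1, :5] = 1.0  # detected in 5% of each group
        m[1, 100:105] = 1.0
        cm = toy_counts(m)
        res = wilcoxon_de(lognormalize(cm), np.arange(100), np.arange(100, 200),
                          cm.genes)
        assert not res.table.set_index("gene").loc["g1", "tested"]

    def test_empty_group_rejected(self):
        cm = toy_counts(np.ones((2, 4)))
        with pytest.raises(ValueError):
            wilcoxon_de(lognormalize(cm), np.array([]), np.arange(4), cm.genes)


class TestFindMarkers:
    def test_planted_cluster_markers_recovered(self):
        rng = np.random.default_rng(4)
        n_per = 60
        labels = np.repeat(["a", "b", "c"], n_per)
        m = rng.poisson(2.0, size=(12, 3 * n_per)).astype(float)
        # one marker per cluster, balanced so library sizes stay comparable
        m[8, labels == "c"] += 20.0
        m[9, labels == "a"] += 20.0
        m[10, labels == "b"] += 20.0
        m[11] = rng.poisson(5.0, 3 * n_per)  # uniform
        cm = toy_counts(m)
        markers = find_markers(lognormalize(cm), labels, cm.genes)
        assert "g9" in markers["a"] and "g9" not in markers["b"]
        assert "g10" in markers["b"] and "g10" not in markers["a"]
        assert "g8" in markers["c"] and "g8" not in markers["a"]
        for cl in markers:
            assert "g11" not in markers[cl]

    def test_singleton_cluster_skipped_with_warning(self):
        m = np.ones((3, 5))
        labels = ["a", "a", "a", "a", "b"]
        with pytest.warns(UserWarning, match="< 2 cells"):
            markers = find_markers(lognormalize(toy_counts(m)), labels,
                                   ["g0", "g1", "g2"])
        assert markers["b"] == []


class TestApoeHigh:
    def make_norm(self, levels):
        m = np.vstack([np.asarray(levels, float), np.full(len(levels), 5.0)])
        norm = sp.csr_matrix(m)
        meta = pd.DataFrame({"cluster_id": ["ct"] * len(levels)})
        return norm, meta

    def test_all_equal_none_high(self):
        norm, meta = self.make_norm([2.0] * 10)
        high = classify_apoe_high(norm, meta, ["Apoe", "other"])
        assert not high.any()

    def test_rule_arithmetic(self):
        levels = [1.0, 1.5, 2.0, 2.5, 3.0, 5.0, 3.9]
        norm, meta = self.make_norm(levels)
        high = classify_apoe_high(norm, meta, ["Apoe", "other"])
        # independent evaluation of the stated rule
        cut = np.median(levels) + 2.0 * np.std(levels, ddof=1)
        assert list(high) == [lv > cut for lv in levels]

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        levels = rng.exponential(2.0, 50)
        norm, meta = self.make_norm(levels)
        high = classify_apoe_high(norm, meta, ["Apoe", "other"])
        perm = rng.permutation(50)
        norm2, meta2 = self.make_norm(levels[perm])
        high2 = classify_apoe_high(norm2, meta2, ["Apoe", "other"])
        assert np.array_equal(high[perm], high2)

    def test_tiny_cell_type_warns_not_high(self):
        norm, meta = self.make_norm([1.0, 100.0])
        with pytest.warns(UserWarning):
            high = classify_apoe_high(norm, meta, ["Apoe", "other"])
        assert not high.any()


def de_table(genes, de_genes, sign=1.0):
    """Synthetic DEResult-like table: listed genes significant with given sign."""
    from hippoexc.genes import DEResult
    rows = []
    for g in genes:
        is_de = g in de_genes
        rows.append({"gene": g,
                     "log_fc": sign * (1.0 if is_de else 0.0) + (0.01 if not is_de else 0),
                     "pct_1": 0.5, "pct_2": 0.5,
                     "p_raw": 0.001 if is_de else 0.9,
                     "p_adj": 0.01 if is_de else 0.95,
                     "tested": True})
    return DEResult(pd.DataFrame(rows))


class TestMultilevelFilter:
    GENES = [f"g{i}" for i in range(6)]

    def tables(self, **de_sets):
        return {k: de_table(self.GENES, de_sets.get(k, set())) for k in CONTRAST_KEYS}

    def test_empty_tables_empty_candidates(self):
        rep = multilevel_filter(self.tables())
        assert rep.candidates == []

    def test_full_pattern_is_candidate(self):
        rep = multilevel_filter(self.tables(
            e4_vs_e3_05mo={"g0"}, e4_vs_e3_10mo={"g0"},
            apoehigh_e4_vs_e3_10mo={"g0"}, e3_20mo_vs_e3_05mo={"g0"}))
        assert rep.candidates == ["g0"]

    def test_single_flag_flip_rejects(self):
        # same gene but additionally DE at 20 months -> fails criterion 5
        rep = multilevel_filter(self.tables(
            e4_vs_e3_05mo={"g0"}, e4_vs_e3_10mo={"g0"},
            apoehigh_e4_vs_e3_10mo={"g0"}, e3_20mo_vs_e3_05mo={"g0"},
            e4_vs_e3_20mo={"g0"}))
        assert rep.candidates == []
        assert not rep.flags.loc["g0", "c5_not_de_e4_vs_e3_20mo"]
        assert rep.flags.loc["g0", "c4_not_de_fe4_5_10mo"]

    def test_successive_counts_non_increasing(self):
        rep = multilevel_filter(self.tables(
            e4_vs_e3_05mo={"g0", "g1", "g2"}, e4_vs_e3_10mo={"g0", "g1"},
            apoehigh_e4_vs_e3_10mo={"g0"}, e3_20mo_vs_e3_05mo={"g0"}))
        counts = rep.successive_counts.to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert counts[0] == 3 and counts[-1] == 1

    def test_direction_consistency_enforced(self):
        tabs = self.tables(e4_vs_e3_05mo={"g0"}, apoehigh_e4_vs_e3_10mo={"g0"},
                           e3_20mo_vs_e3_05mo={"g0"})
        tabs["e4_vs_e3_10mo"] = de_table(self.GENES, {"g0"}, sign=-1.0)
        rep = multilevel_filter(tabs)
        assert rep.candidates == []

    def test_missing_contrast_named(self):
        tabs = self.tables()
        del tabs["e4_vs_e3_20mo"]
        with pytest.raises(ValueError, match="e4_vs_e3_20mo"):
            multilevel_filter(tabs)

    def test_invariant_to_gene_and_row_order(self):
        tabs1 = self.tables(e4_vs_e3_05mo={"g0"}, e4_vs_e3_10mo={"g0"},
                            apoehigh_e4_vs_e3_10mo={"g0"},
                            e3_20mo_vs_e3_05mo={"g0"})
        tabs2 = {k: type(v)(v.table.iloc[::-1].reset_index(drop=True))
                 for k, v in tabs1.items()}
        assert multilevel_filter(tabs1).candidates == \
            multilevel_filter(tabs2).candidates


class TestEndToEndRecovery:
    def test_planted_patterns_recovered_exactly(self):
        planted, truth = standard_planted_patterns(1.0)
        cfg = SynthCountConfig(n_genes=80, cells_per_group=800,
                               planted_genes=planted, gene_names=tuple(planted),
                               seed=6)
        cm, meta = simulate_counts(cfg)
        norm = lognormalize(cm)
        tables = standard_contrasts(norm, meta, cm.genes)
        rep = multilevel_filter(tables)
        # at desk scale the deterministic fail patterns must all be excluded
        # and both full-pattern candidates recovered
        assert set(truth).issubset(set(rep.candidates))
        for g in planted:
            if g not in truth:
                assert g not in rep.candidates


class TestJaccardAndMatching:
    def test_jaccard_reference_values(self):
        assert jaccard_similarity({"a"}, {"a"}) == 1.0
        assert jaccard_similarity({"a"}, {"b"}) == 0.0
        assert jaccard_similarity({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard_similarity(set(), set()) == 0.0

    def test_identity_matrix_identity_mapping(self):
        sim = pd.DataFrame(np.eye(3), index=["a", "b", "c"], columns=["x", "y", "z"])
        mapping, unmatched = greedy_cluster_match(sim)
        assert mapping == {"a": "x", "b": "y", "c": "z"}
        assert unmatched == []

    def test_ambiguous_row_follows_greedy_rule(self):
        sim = pd.DataFrame([[0.8, 0.8, 0.1],
                            [0.7, 0.2, 0.3],
                            [0.1, 0.1, 0.9]],
                           index=["a", "b", "c"], columns=["x", "y", "z"])
        sizes_new = {"a": 10, "b": 20, "c": 5}
        sizes_ref = {"x": 20, "y": 10, "z": 5}
        # hand execution: (c,z)=0.9 first; then 0.8 tie (a,x)/(a,y) broken by
        # relative size difference -> (a,y); then b -> x
        mapping, unmatched = greedy_cluster_match(sim, sizes_new, sizes_ref)
        assert mapping == {"c": "z", "a": "y", "b": "x"}

    def test_all_zero_matrix_unmatched(self):
        sim = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["x", "y"])
        mapping, unmatched = greedy_cluster_match(sim)
        assert mapping == {}
        assert unmatched == ["a", "b"]
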