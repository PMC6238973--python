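from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mirhinge import (
    CellTypeDataset,
    ExpressionMatrix,
    celltype_differential_expression,
    integrate_binding_sites,
    load_candidate_fixture,
    overlap_enrichment,
    refine_candidates,
    summarize_candidates,
)
from mirhinge.stroma import RefinedSet


def _dataset(rows, n_stroma, n_tumor, paired=False, name="d"):
    cols = [f"st{i}" for i in range(n_stroma)] + [f"tu{i}" for i in range(n_tumor)]
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df.columns = cols
    cell_type = {c: ("stroma" if c.startswith("st") else "tumor") for c in cols}
    patient = None
    if paired:
        patient = {f"st{i}": f"p{i}" for i in range(n_stroma)}
        patient.update({f"tu{i}": f"p{i}" for i in range(n_tumor)})
    return CellTypeDataset(name=name, expression=ExpressionMatrix(df),
                           cell_type=cell_type, patient=patient)


def _de(rows, dataset="d"):
    return pd.DataFrame([
        {"feature_id": f, "dataset": dataset, "mode": "unpaired",
         "mean_stroma": 0, "mean_tumor": 0, "t": t, "p": q, "q": q,
         "direction": d}
        for f, q, d, t in rows])


class TestCellTypeDE:
    def test_strong_stroma_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        up = base.copy()
        up[:6] += 5.0
        d = _dataset({"hit": up, "null": base}, 6, 6)
        de = celltype_differential_expression(d)
        rec = de.set_index("feature_id").loc["hit"]
        assert rec["direction"] == "up" and rec["q"] < 0.01

    def test_identical_distributions_near_null(self):
        rng = np.random.default_rng(1)
        d = _dataset({f"f{i}": rng.normal(size=10) for i in range(5)}, 5, 5)
        de = celltype_differential_expression(d)
        assert de["q"].min() > 0.05

    def test_paired_beats_unpaired_on_constant_shift(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 3, size=4)  # large between-patient spread
        stroma = base + 1.0              # constant within-pair shift
        vals = {"f": list(stroma) + list(base)}
        paired = celltype_differential_expression(
            _dataset(vals, 4, 4, paired=True))
        unpaired = celltype_differential_expression(_dataset(vals, 4, 4))
        assert paired.iloc[0]["mode"] == "paired"
        assert paired.iloc[0]["p"] <= unpaired.iloc[0]["p"]

    def test_single_cell_type_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["a", "b"])
        with pytest.raises(ValueError):
            CellTypeDataset("d", ExpressionMatrix(df),
                            {"a": "tumor", "b": "tumor"})

    def test_duplicate_patient_cell_type_rejected(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"],
                          columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            CellTypeDataset("d", ExpressionMatrix(df),
                            {"a": "stroma", "b": "stroma", "c": "tumor"},
                            patient={"a": "p1", "b": "p1", "c": "p1"})


class TestOverlapEnrichment:
    def test_identical_sets_closed_form(self):
        universe = {f"g{i}" for i in range(100)}
        s = {f"g{i}" for i in range(10)}
        from math import comb
        assert overlap_enrichment(s, s, universe) == pytest.approx(
            1 / comb(100, 10), rel=1e-9)

    def test_disjoint_sets_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(5, 10)}
        assert overlap_enrichment(a, b, universe) == pytest.approx(1.0)

    def test_universe_equals_candidates(self):
        u = {"a", "b", "c"}
        assert overlap_enrichment(u, {"a"}, u) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(), set(), set())

    def test_matches_exhaustive_enumeration_small_universe(self):
        N, n_up, n_cand = 12, 5, 4
        universe = [f"g{i}" for i in range(N)]
        up = set(universe[:n_up])
        cand = set(universe[2:2 + n_cand])
        k = len(cand & up)
        total = hits = 0
        for draw in combinations(range(N), n_cand):
            total += 1
            hits += len({universe[i] for i in draw} & up) >= k
        p = overlap_enrichment(cand, up, set(universe))
        assert p == pytest.approx(hits / total, rel=1e-9)


class TestRefineCandidates:
    def _pairs(self):
        return pd.DataFrame({
            "mirna": ["mA", "mA", "mB", "mC"],
            "gene": ["g1", "g2", "g1", "g3"],
        })

    def test_gene_up_in_one_of_three_datasets_kept(self):
        gene_de = [
            _de([("g1", 0.5, "up", 1.0)], "d1"),
            _de([("g1", 0.01, "up", 3.0), ("g2", 0.8, "down", -0.1)], "d2"),
            _de([("g1", 0.9, "down", -0.5)], "d3"),
        ]
        mirna_de = [_de([("mA", 0.01, "down", -4.0),
                         ("mB", 0.01, "down", -3.0),
                         ("mC", 0.01, "up", 2.0)], "dm")]
        out = refine_candidates(self._pairs(), gene_de, mirna_de)
        assert out.genes == {"g1"}
        assert "mC" not in out.mirnas  # stroma-up miRNA dropped
        assert set(zip(out.pairs["mirna"], out.pairs["gene"])) == {
            ("mA", "g1"), ("mB", "g1")}

    def test_mirna_top_k_rescue(self):
        gene_de = [_de([("g1", 0.01, "up", 3.0)])]
        # mA misses significance but is the strongest down-regulated miRNA
        mirna_de = [_de([("mA", 0.2, "down", -5.0),
                         ("mX", 0.2, "down", -1.0)], "dm")]
        out = refine_candidates(self._pairs(), gene_de, mirna_de, top_k=1)
        assert "mA" in out.mirnas
        out2 = refine_candidates(self._pairs(), gene_de, mirna_de, top_k=0)
        assert "mA" not in out2.mirnas

    def test_gene_up_nowhere_drops_its_pairs(self):
        gene_de = [_de([("g1", 0.5, "up", 0.1), ("g2", 0.01, "down", -3.0)])]
        mirna_de = [_de([("mA", 0.01, "down", -3.0)])]
        out = refine_candidates(self._pairs(), gene_de, mirna_de)
        assert out.genes == set() and len(out.pairs) == 0

    def test_monotone_in_added_datasets(self):
        gene_de1 = [_de([("g1", 0.01, "up", 3.0)])]
        extra = _de([("g2", 0.01, "up", 2.0)], "d2")
        mirna_de = [_de([("mA", 0.01, "down", -3.0)])]
        out1 = refine_candidates(self._pairs(), gene_de1, mirna_de)
        out2 = refine_candidates(self._pairs(), gene_de1 + [extra], mirna_de)
        assert out1.genes <= out2.genes


class TestBindingSiteIntegration:
    def test_reproduces_reference_refined_table(self):
        fixture = load_candidate_fixture()
        model = fixture[fixture["identification_method"] == "combined_model"]
        extra = fixture[fixture["identification_method"] == "binding_site"]
        refined = RefinedSet(
            genes=set(fixture["gene_symbol"]),
            mirnas=set(fixture["mirna"]),
            pairs=model.rename(columns={"gene_symbol": "gene"})[
                ["mirna", "gene"]],
        )
        preds = model.rename(columns={"gene_symbol": "gene"})[["mirna", "gene"]]
        sites = extra.rename(columns={"gene_symbol": "gene"})[
            ["mirna", "gene"]].copy()
        sites.insert(0, "tool", "TargetScan")
        names = dict(zip(fixture["gene_symbol"], fixture["gene_name"]))
        table = integrate_binding_sites(refined, preds, sites,
                                        gene_names=names)
        assert len(table) == 39
        got = set(map(tuple, table[["mirna", "gene_symbol",
                                    "identification_method"]].to_numpy()))
        want = set(map(tuple, fixture[["mirna", "gene_symbol",
                                       "identification_method"]].to_numpy()))
        assert got == want
        assert (table.set_index(["mirna", "gene_symbol"])["gene_name"]
                .to_dict() ==
                fixture.set_index(["mirna", "gene_symbol"])["gene_name"]
                .to_dict())

    def test_combo_without_tool_support_excluded(self):
        refined = RefinedSet(genes={"g1", "g2"}, mirnas={"m"},
                             pairs=pd.DataFrame({"mirna": ["m"],
                                                 "gene": ["g1"]}))
        preds = pd.DataFrame({"mirna": ["m"], "gene": ["g1"]})
        sites = pd.DataFrame(columns=["tool", "mirna", "gene"])
        table = integrate_binding_sites(refined, preds, sites)
        assert list(table["gene_symbol"]) == ["g1"]

    def test_model_pair_also_in_site_table_not_duplicated(self):
        refined = RefinedSet(genes={"g1"}, mirnas={"m"},
                             pairs=pd.DataFrame({"mirna": ["m"],
                                                 "gene": ["g1"]}))
        preds = pd.DataFrame({"mirna": ["m"], "gene": ["g1"]})
        sites = pd.DataFrame({"tool": ["PITA"], "mirna": ["m"],
                              "gene": ["g1"]})
        table = integrate_binding_sites(refined, preds, sites)
        assert len(table) == 1
        assert table.iloc[0]["identification_method"] == "combined_model"

    def test_no_pair_emitted_twice(self):
        refined = RefinedSet(genes={"g1", "g2", "g3"}, mirnas={"m1", "m2"},
                             pairs=pd.DataFrame({"mirna": ["m1"],
                                                 "gene": ["g1"]}))
        preds = pd.DataFrame({"mirna": ["m1"], "gene": ["g1"]})
        sites = pd.DataFrame({
            "tool": ["PITA", "RNA22", "TargetScan"],
            "mirna": ["m1", "m1", "m2"],
            "gene": ["g2", "g2", "g3"],
        })
        table = integrate_binding_sites(refined, preds, sites)
        assert not table.duplicated(subset=["mirna", "gene_symbol"]).any()


class TestSummarizeCandidates:
    def test_fixture_counts(self):
        out = summarize_candidates(load_candidate_fixture())
        assert out["n_combined_model"] == 20
        assert out["n_binding_site"] == 19
        assert out["n_total"] == 39

    def test_empty_table_all_zero(self):
        empty = pd.DataFrame(columns=["mirna", "gene_symbol", "gene_name",
                                      "identification_method"])
        out = summarize_candidates(empty)
        assert out["n_total"] == 0 and out["per_mirna"] == {}
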