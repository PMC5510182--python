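"""Ranking, enrichment, RGES, similarity scores, permutation P, matrix IO."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rges import (
    DataError,
    GeneUniverse,
    ProfileMatrix,
    batch_score,
    compute_rges,
    enrichment_score,
    rank_profile,
    read_gct,
    rges_pvalue,
    similarity_score,
)
from rges.core import load_scores, save_scores

from conftest import brute_force_rges, make_profile, make_signature, random_case


class TestRankProfile:
    def test_descending_by_value(self):
        ranked = rank_profile(make_profile({"gA": 2.1, "gB": -0.5, "gC": 0.0,
                                            "gD": 0.9}))
        assert ranked.positions.to_dict() == {"gA": 1, "gD": 2, "gC": 3, "gB": 4}

    def test_ties_break_by_gene_id(self):
        ranked = rank_profile(make_profile({"gB": 1.0, "gA": 1.0}))
        assert ranked.positions["gA"] == 1 and ranked.positions["gB"] == 2

    def test_all_equal_gives_lexicographic_order(self):
        ranked = rank_profile(make_profile({g: 0.0 for g in "edcba"}))
        assert list(ranked.positions.sort_values().index) == list("abcde")

    def test_non_finite_value_names_the_gene(self):
        with pytest.raises(DataError, match="gB"):
            rank_profile(make_profile({"gA": 1.0, "gB": float("nan")}))


class TestEnrichmentScore:
    @pytest.mark.parametrize("geneset, expected", [
        ({"g1"}, 0.75),           # top gene: a = 1 - 1/4
        ({"g4"}, -1.0),           # bottom gene: b = 1
        ({"g1", "g2", "g3", "g4"}, -0.25),  # full universe: -1/n
    ])
    def test_worked_examples_n4(self, geneset, expected):
        ranked = rank_profile(make_profile({"g1": 4.0, "g2": 3.0, "g3": 2.0,
                                            "g4": 1.0}))
        assert enrichment_score(ranked, geneset) == pytest.approx(expected, abs=0)

    def test_empty_or_foreign_geneset_rejected(self, universe4):
        ranked = rank_profile(make_profile({g: 1.0 for g in universe4.genes}))
        with pytest.raises(DataError, match="empty"):
            enrichment_score(ranked, set())
        with pytest.raises(DataError, match="outside"):
            enrichment_score(ranked, {"gZ"})

    def test_bounded_by_one(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            genes, values, up, down = random_case(rng)
            ranked = rank_profile(make_profile(values))
            assert abs(enrichment_score(ranked, up)) <= 1.0
            assert abs(enrichment_score(ranked, down)) <= 1.0


class TestComputeRGES:
    def test_mimicking_and_reversing_profiles(self, universe4):
        profile = make_profile({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        mimic = make_signature({"g1"}, {"g4"}, universe4)
        rec = compute_rges(profile, mimic, min_overlap=1)
        assert (rec.es_up, rec.es_down, rec.rges) == (0.75, -1.0, 1.75)
        reverse = make_signature({"g4"}, {"g1"}, universe4)
        assert compute_rges(profile, reverse, min_overlap=1).rges == -1.75

    def test_swap_antisymmetry_random(self, ):
        rng = np.random.default_rng(11)
        for _ in range(300):
            genes, values, up, down = random_case(rng)
            universe = GeneUniverse.from_iterable(genes)
            sig = make_signature(up, down, universe)
            p = make_profile(values)
            assert compute_rges(p, sig.swapped(), 1).rges == pytest.approx(
                -compute_rges(p, sig, 1).rges, abs=0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        transforms = [lambda x: 3.0 * x + 7.0, np.exp,
                      lambda x: x ** 3, lambda x: np.arctan(x)]
        for _ in range(100):
            genes, values, up, down = random_case(rng, n_max=20)
            universe = GeneUniverse.from_iterable(genes)
            sig = make_signature(up, down, universe)
            base = compute_rges(make_profile(values), sig, 1)
            for f in transforms:
                tv = {g: float(f(v)) for g, v in values.items()}
                rec = compute_rges(make_profile(tv), sig, 1)
                assert rec == base

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            genes, values, up, down = random_case(rng)
            universe = GeneUniverse.from_iterable(genes)
            sig = make_signature(up, down, universe)
            rec = compute_rges(make_profile(values), sig, 1)
            es_up, es_down, r = brute_force_rges(values, up, down)
            assert rec.es_up == pytest.approx(es_up, abs=1e-12)
            assert rec.es_down == pytest.approx(es_down, abs=1e-12)
            assert rec.rges == pytest.approx(r, abs=1e-12)

    def test_insufficient_overlap_lists_missing_genes(self, universe4):
        profile = make_profile({g: 1.0 for g in universe4.genes})
        sig = make_signature({"g1"}, {"g4"}, universe4)
        with pytest.raises(DataError, match="only 1 up-genes"):
            compute_rges(profile, sig, min_overlap=2)


def _tiny_matrix(universe, quality=(True, False, True)):
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.normal(size=(len(universe.genes), len(quality))),
        index=universe.genes,
        columns=[f"p{i}" for i in range(len(quality))],
    )
    meta = pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(len(quality))],
            "cell_line": "CL1",
            "dose_um": 10.0,
            "time_h": 24.0,
            "quality_flag": list(quality),
        },
        index=pd.Index([f"p{i}" for i in range(len(quality))], name="profile_id"),
    )
    return ProfileMatrix(universe, values, meta)


class TestBatchScore:
    def test_quality_filter_and_order(self, universe4):
        m = _tiny_matrix(universe4)
        sig = make_signature({"g1"}, {"g4"}, universe4)
        gold = batch_score(m, sig, quality_only=True, min_overlap=1)
        assert list(gold["profile_id"]) == ["p0", "p2"]
        everything = batch_score(m, sig, quality_only=False, min_overlap=1)
        assert list(everything["profile_id"]) == ["p0", "p1", "p2"]

    def test_identical_profiles_get_identical_scores(self, universe4):
        values = pd.DataFrame({"pa": [4.0, 3.0, 2.0, 1.0],
                               "pb": [4.0, 3.0, 2.0, 1.0]},
                              index=universe4.genes)
        meta = pd.DataFrame({"compound_id": ["c", "c"], "cell_line": "CL1",
                             "dose_um": 10.0, "time_h": 24.0,
                             "quality_flag": True},
                            index=pd.Index(["pa", "pb"], name="profile_id"))
        m = ProfileMatrix(universe4, values, meta)
        sig = make_signature({"g1"}, {"g4"}, universe4)
        out = batch_score(m, sig, min_overlap=1)
        assert out.loc[0, "rges"] == out.loc[1, "rges"]

    def test_all_filtered_out_is_an_error(self, universe4):
        m = _tiny_matrix(universe4, quality=(False, False))
        sig = make_signature({"g1"}, {"g4"}, universe4)
        with pytest.raises(DataError, match="filtered"):
            batch_score(m, sig, quality_only=True, min_overlap=1)


class TestSimilarityScore:
    def test_self_correlation_is_one(self, universe4):
        sig = make_signature({"g1"}, {"g3", "g4"}, universe4)
        values = {g: sig.log2fc(g) if g in sig.genes else 0.1 for g in universe4.genes}
        assert similarity_score(make_profile(values), sig, "pearson") == pytest.approx(1.0)

    def test_negated_values_give_cosine_minus_one(self, universe4):
        sig = make_signature({"g1"}, {"g3", "g4"}, universe4)
        values = {g: -sig.log2fc(g) if g in sig.genes else 0.1 for g in universe4.genes}
        assert similarity_score(make_profile(values), sig, "cosine") == pytest.approx(-1.0)

    def test_reversed_ranks_give_spearman_minus_one(self, universe4):
        stats = {"g1": (2.0, 1e-6), "g2": (-2.0, 1e-6), "g3": (1.0, 1e-6)}
        from rges import DiseaseSignature
        sig = DiseaseSignature(frozenset({"g1", "g3"}), frozenset({"g2"}),
                               stats, universe4)
        values = {"g1": -1.0, "g2": 3.0, "g3": -0.5, "g4": 0.0}
        assert similarity_score(make_profile(values), sig, "spearman") == pytest.approx(-1.0)

    def test_zero_variance_and_zero_norm_errors(self, universe4):
        sig = make_signature({"g1"}, {"g3", "g4"}, universe4)
        flat = make_profile({g: 1.0 for g in universe4.genes})
        with pytest.raises(DataError, match="zero-variance"):
            similarity_score(flat, sig, "pearson")
        zero = make_profile({g: 0.0 for g in universe4.genes})
        with pytest.raises(DataError, match="zero-norm"):
            similarity_score(zero, sig, "cosine")


class TestRgesPvalue:
    def test_reproducible_under_seed(self, universe4):
        profile = make_profile({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        sig = make_signature({"g1"}, {"g4"}, universe4)
        p1 = rges_pvalue(profile, sig, n_perm=500, seed=42, min_overlap=1)
        p2 = rges_pvalue(profile, sig, n_perm=500, seed=42, min_overlap=1)
        assert p1 == p2

    def test_matches_exhaustive_null_on_tiny_universe(self):
        genes = [f"g{i}" for i in range(6)]
        universe = GeneUniverse.from_iterable(genes)
        values = {g: float(6 - i) for i, g in enumerate(genes)}
        profile = make_profile(values)
        sig = make_signature({"g0"}, {"g5"}, universe)
        obs = abs(compute_rges(profile, sig, 1).rges)
        # enumerate all 30 ordered disjoint (up, down) singleton pairs
        hits = total = 0
        for up, down in itertools.permutations(genes, 2):
            s = make_signature({up}, {down}, universe)
            total += 1
            hits += abs(compute_rges(profile, s, 1).rges) >= obs - 1e-12
        exact = hits / total
        p = rges_pvalue(profile, sig, n_perm=20000, seed=7, min_overlap=1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_null_score_is_never_extreme(self):
        # symmetric values around 0 -> rges 0 for a symmetric signature
        genes = [f"g{i}" for i in range(8)]
        universe = GeneUniverse.from_iterable(genes)
        values = {g: float(8 - i) for i, g in enumerate(genes)}
        profile = make_profile(values)
        sig = make_signature({"g0", "g7"}, {"g1", "g6"}, universe)
        rec = compute_rges(profile, sig, min_overlap=1)
        p = rges_pvalue(profile, sig, n_perm=2000, seed=1, min_overlap=1)
        assert abs(rec.rges) < 0.3 and p > 0.5


class TestMatrixIO:
    def test_tsv_roundtrip(self, tmp_path, universe4):
        m = _tiny_matrix(universe4)
        m.save(tmp_path / "v.tsv", tmp_path / "m.tsv")
        back = ProfileMatrix.load(tmp_path / "v.tsv", tmp_path / "m.tsv", universe4)
        pd.testing.assert_frame_equal(back.values, m.values)
        assert list(back.meta["quality_flag"]) == [True, False, True]

    def test_score_table_roundtrip(self, tmp_path, universe4):
        m = _tiny_matrix(universe4)
        sig = make_signature({"g1"}, {"g4"}, universe4)
        scores = batch_score(m, sig, min_overlap=1)
        save_scores(scores, tmp_path / "s.tsv")
        back = load_scores(tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back, scores)

    def test_gct_reader(self, tmp_path):
        gct = (
            "#1.3\n"
            "3\t2\t1\t4\n"
            "id\tdesc\tP1\tP2\n"
            "pert_id\t-\tcpdA\tcpdB\n"
            "cell_id\t-\tMCF7\tMCF7\n"
            "pert_dose\t-\t10\t5\n"
            "pert_time\t-\t24\t6\n"
            "gA\tfoo\t1.5\t-0.5\n"
            "gB\tbar\t0.0\t2.0\n"
            "gC\tbaz\t-1.0\t0.25\n"
        )
        path = tmp_path / "m.gct"
        path.write_text(gct)
        m = read_gct(path)
        assert m.universe.genes == ("gA", "gB", "gC")
        assert m.values.loc["gC", "P2"] == 0.25
        meta = m.meta.loc["P2"]
        assert (meta["compound_id"], meta["dose_um"], meta["time_h"]) == ("cpdB", 5.0, 6.0)
        assert bool(meta["quality_flag"])  # is_gold missing -> defaults to true

    def test_mismatched_universe_rejected(self, universe4):
        values = pd.DataFrame({"p0": [1.0, 2.0]}, index=["g1", "gZ"])
        meta = pd.DataFrame({"compound_id": ["c"], "cell_line": ["x"],
                             "dose_um": [1.0], "time_h": [6.0],
                             "quality_flag": [True]},
                            index=pd.Index(["p0"], name="profile_id"))
        with pytest.raises(DataError, match="universe"):
            ProfileMatrix(universe4, values, meta)
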