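"""Top-N ranking, cross-table set logic, and hypergeometric enrichment."""

import itertools
import math
from importlib import resources

import pandas as pd
import pytest

from cochlear_aging import (
    GeneAnnotation,
    StudyDesign,
    concordant_subset,
    exclusive_top,
    gen_expression_study,
    hypergeom_enrichment,
    rank_top_common,
)
from cochlear_aging.degs import classify_deg
from cochlear_aging.errors import ConfigurationError
from cochlear_aging.genesets import enrich_categories


def deg_frame(entries):
    """Toy DEG table from {gene: (log2fc, status)}."""
    return pd.DataFrame(
        {
            "gene": list(entries),
            "log2fc": [v[0] for v in entries.values()],
            "status": [v[1] for v in entries.values()],
        }
    ).set_index("gene", drop=False)


class TestRankTopCommon:
    def test_min_magnitude_ranking(self):
        a = deg_frame({"g1": (3.0, "up"), "g2": (2.0, "up")})
        b = deg_frame({"g1": (1.0, "up"), "g2": (2.0, "up")})
        # min(|fc|) pairs: g1 -> 1, g2 -> 2; descending puts g2 first
        assert rank_top_common(a, b, "up", 200) == ["g2", "g1"]

    def test_no_padding_and_membership(self):
        a = deg_frame({f"g{i}": (2.0, "up") for i in range(5)} | {"h": (3.0, "ns")})
        b = deg_frame({f"g{i}": (2.0, "up") for i in range(5)} | {"h": (3.0, "up")})
        out = rank_top_common(a, b, "up", 200)
        assert len(out) == 5  # only 5 qualify; "h" is ns in table a
        assert "h" not in out

    def test_symmetric_as_sets(self, small_study):
        ihc, _ = classify_deg(small_study.rpkm, "IHC", "young", "aged")
        ohc, _ = classify_deg(small_study.rpkm, "OHC", "young", "aged")
        ab = rank_top_common(ihc, ohc, "down", 200)
        ba = rank_top_common(ohc, ihc, "down", 200)
        assert set(ab) == set(ba)

    def test_invalid_n(self):
        with pytest.raises(ConfigurationError):
            rank_top_common(deg_frame({}), deg_frame({}), "up", 0)


class TestConcordantSubset:
    def test_empty_reference(self):
        assert concordant_subset(["g1"], deg_frame({}), "up") == []

    def test_opposite_direction_excluded_order_preserved(self):
        ref = deg_frame({"g1": (2.0, "down"), "g2": (2.0, "up"), "g3": (1.5, "up")})
        assert concordant_subset(["g3", "g1", "g2"], ref, "up") == ["g3", "g2"]

    def test_planted_overlap_by_construction(self):
        shared = [f"Gene{i:05d}" for i in range(1, 8)]
        ihc_only = [f"Gene{i:05d}" for i in range(10, 40)]
        svc_only = [f"Gene{i:05d}" for i in range(50, 60)]
        design = StudyDesign(
            n_genes=400,
            frac_up=0.0,
            frac_down=0.0,
            nb_dispersion=0.02,
            mean_log_expression=3.0,
            sd_log_expression=1.0,
            seed=5,
            planted={
                "IHC": (shared + ihc_only, []),
                "OHC": (shared + ihc_only, []),
                "SVC": (shared + svc_only, []),
            },
        )
        study = gen_expression_study(design)
        ihc, _ = classify_deg(study.rpkm, "IHC", "young", "aged")
        ohc, _ = classify_deg(study.rpkm, "OHC", "young", "aged")
        svc, _ = classify_deg(study.rpkm, "SVC", "young", "aged")
        common = rank_top_common(ihc, ohc, "up", 200)
        concordant = concordant_subset(common, svc, "up")
        # exactly the 7 genes planted in all three cell types are concordant
        assert set(concordant) == set(shared)


class TestExclusiveTop:
    def test_gene_changed_in_both_excluded(self):
        a = deg_frame({"g1": (2.0, "up"), "g2": (3.0, "up")})
        b = deg_frame({"g1": (2.0, "up"), "g2": (0.1, "ns")})
        assert exclusive_top(a, b, "up", 50) == ["g2"]

    def test_empty_other_equals_plain_top_n(self):
        a = deg_frame({"g1": (1.5, "up"), "g2": (3.0, "up"), "g3": (2.0, "up")})
        assert exclusive_top(a, deg_frame({}), "up", 2) == ["g2", "g3"]

    def test_intersection_mode(self):
        a = deg_frame({"g1": (2.0, "up"), "g2": (3.0, "up")})
        b = deg_frame({"g1": (2.0, "up"), "g2": (0.1, "ns")})
        assert exclusive_top(a, b, "up", 50, mode="intersection") == ["g1"]

    def test_disjoint_from_common_list(self, small_study):
        ihc, _ = classify_deg(small_study.rpkm, "IHC", "young", "aged")
        ohc, _ = classify_deg(small_study.rpkm, "OHC", "young", "aged")
        for d in ("up", "down"):
            common = set(rank_top_common(ihc, ohc, d, 10**6))
            excl = set(exclusive_top(ihc, ohc, d, 10**6))
            assert not (common & excl)


def brute_force_upper_tail(m: int, k_cat: int, n_hits: int, observed: int) -> float:
    """Exhaustive P(X >= observed) by enumerating all draws of n_hits from m."""
    universe = range(m)
    category = set(range(k_cat))
    total = hits = 0
    for draw in itertools.combinations(universe, n_hits):
        total += 1
        if len(category.intersection(draw)) >= observed:
            hits += 1
    return hits / total


class TestHypergeomEnrichment:
    def test_worked_example(self):
        universe = set(range(10))
        category = set(range(5))
        hit = {0, 1, 2, 3}
        p, overlap = hypergeom_enrichment(hit, category, universe)
        assert overlap == 4
        assert p == pytest.approx(5 / 210)  # C(5,4)C(5,0)/C(10,4)

    def test_category_equals_universe_gives_p_one(self):
        u = {f"g{i}" for i in range(8)}
        p, overlap = hypergeom_enrichment({"g1", "g2"}, u, u)
        assert p == pytest.approx(1.0)
        assert overlap == 2

    def test_validation_errors(self):
        with pytest.raises(ConfigurationError):
            hypergeom_enrichment(set(), set(), set())
        with pytest.raises(ConfigurationError):
            hypergeom_enrichment({"x"}, set(), {"y"})

    def test_matches_exhaustive_enumeration_on_small_universes(self, rng):
        for _ in range(15):
            m = int(rng.integers(4, 13))
            k_cat = int(rng.integers(1, m + 1))
            n_hits = int(rng.integers(1, m + 1))
            universe = set(range(m))
            category = set(range(k_cat))
            hit = set(rng.choice(m, size=n_hits, replace=False).tolist())
            p, overlap = hypergeom_enrichment(hit, category, universe)
            expected = brute_force_upper_tail(m, k_cat, n_hits, overlap)
            assert p == pytest.approx(expected, rel=1e-9), (m, k_cat, n_hits, overlap)


class TestAnnotation:
    def test_demo_annotation_lookup_is_total(self):
        path = resources.files("cochlear_aging") / "data" / "demo_annotations.tsv"
        ann = GeneAnnotation.from_tsv(path)
        assert "oxidative stress" in ann["Sod1"]
        assert ann["NotAGene"] == frozenset()
        assert len(ann.categories()) >= 5

    def test_enrichment_table_orders_by_p(self):
        ann = GeneAnnotation({"a": {"X"}, "b": {"X"}, "c": {"Y"}, "d": {"Y"}})
        universe = {"a", "b", "c", "d", "e", "f"}
        out = enrich_categories({"a", "b"}, ann, universe)
        assert list(out["category"]) == ["X", "Y"]
        assert (out["fdr"] >= out["p"] - 1e-15).all()
        assert math.isclose(out.loc[0, "p"], 1 / 15)  # C(2,2)C(4,0)/C(6,2)
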