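"""Enrichment scores, matched resampling, hypergeometric tests, histograms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methaplo.blocks import Block
from methaplo.enrichment import (
    block_comod_enrichment,
    classify_enhancers,
    enrichment_score,
    gene_comod_enrichment,
    hypergeometric_overlap_test,
    midpoint_distance_histogram,
    sampled_expected_overlap,
)
from methaplo.io import GenomicElementSet


class TestEnrichmentScore:
    def test_twofold_concentration(self):
        # element holds 10% of CpGs but 20% of calls -> log2(2) = 1
        assert enrichment_score(20, 100, 10, 100) == pytest.approx(1.0)

    def test_proportional_element_scores_zero(self):
        assert enrichment_score(10, 100, 10, 100) == pytest.approx(0.0)

    def test_zero_observed_is_neg_inf(self):
        assert enrichment_score(0, 100, 10, 100) == -math.inf

    def test_zero_expected_flagged_nan(self):
        assert math.isnan(enrichment_score(0, 100, 0, 100))

    def test_shift_free(self):
        a = enrichment_score(7, 50, 13, 200)
        b = enrichment_score(14, 100, 26, 400)
        assert a == pytest.approx(b)


class TestGeneComod:
    def _setup(self):
        cpgs = [("chr1", p) for p in range(10, 1010, 10)]  # 100 CpGs
        return cpgs

    def test_concentrated_gene(self):
        cpgs = self._setup()
        # gene covers CpGs at 10..100 (10% of CpGs) and holds all co-sites
        genes = [("chr1", 0, 100, "gA"), ("chr1", 100, 1000, "gB")]
        co = {("chr1", 10), ("chr1", 50), ("chr1", 100)}
        df = gene_comod_enrichment(genes, co, cpgs)
        ga = df.set_index("gene").loc["gA"]
        assert ga["score"] == pytest.approx(math.log2(10))
        assert df.iloc[0]["gene"] == "gA"  # ranked first

    def test_uniform_spread_scores_near_zero(self):
        cpgs = self._setup()
        genes = [("chr1", 0, 500, "gA"), ("chr1", 500, 1000, "gB")]
        co = set(cpgs[::2])  # every other CpG everywhere
        df = gene_comod_enrichment(genes, co, cpgs)
        assert np.allclose(df["score"], 0.0, atol=0.1)

    def test_empty_co_sites_flagged(self):
        cpgs = self._setup()
        df = gene_comod_enrichment([("chr1", 0, 100, "gA")], set(), cpgs)
        assert math.isnan(df.iloc[0]["score"])
        assert not df.iloc[0]["enriched"]


class TestHypergeometric:
    def test_worked_value(self):
        assert hypergeometric_overlap_test(10, 4, 5, 4) == pytest.approx(6 / 252)

    def test_zero_observed_certain(self):
        assert hypergeometric_overlap_test(10, 4, 5, 0) == pytest.approx(1.0)

    def test_matches_enumeration_small_populations(self):
        for N in range(2, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    # enumerate all C(N, n) draws directly
                    pop = [1] * K + [0] * (N - K)
                    tails = {}
                    total = 0
                    for combo in itertools.combinations(range(N), n):
                        x = sum(pop[i] for i in combo)
                        tails[x] = tails.get(x, 0) + 1
                        total += 1
                    for x in range(min(K, n) + 1):
                        exact = sum(v for k, v in tails.items() if k >= x) / total
                        assert hypergeometric_overlap_test(N, K, n, x) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap_test(10, 4, 5, 5)
        with pytest.raises(ValueError):
            hypergeometric_overlap_test(10, 12, 5, 1)


def _slots(n, length=100, gap=1000):
    return [("chr1", i * (length + gap), i * (length + gap) + length) for i in range(n)]


class TestSampledOverlap:
    def test_saturated_target_gives_p_one(self):
        uni = _slots(10)
        target = GenomicElementSet.from_tuples("t", uni)
        templates = _slots(3)
        res = sampled_expected_overlap(templates, uni, target, n_reps=200, seed=1)
        assert res.observed == 3
        assert res.p_value == pytest.approx(1.0)

    def test_empirical_p_floor(self):
        # observed above every achievable rep count -> p = 1/(n+1)
        uni = _slots(10)
        templates = [uni[i] for i in range(4)]
        target = GenomicElementSet.from_tuples("t", templates)
        # shrink targets so sampled regions rarely hit them: impossible here,
        # instead use a target disjoint from the universe
        off_target = GenomicElementSet.from_tuples("t", [("chr2", 0, 10)])
        res = sampled_expected_overlap(templates, uni, off_target, n_reps=100, seed=2)
        assert res.observed == 0
        # every rep also scores 0 >= 0, so p = 1; floor applies to the
        # reversed construction below
        assert res.p_value == pytest.approx(1.0)
        on_target = GenomicElementSet.from_tuples(
            "t", [("chr1", s + 40, s + 60) for _, s, e in templates]
        )
        # make only template slots targets but exclude them from the universe
        uni_rest = _slots(10)[4:]
        res2 = sampled_expected_overlap(templates, uni_rest, on_target, n_reps=100, seed=3)
        assert res2.observed == 4
        assert res2.p_value == pytest.approx(1 / 101)

    def test_matches_hypergeometric_on_slot_universe(self):
        # 10 equal slots, 4 marked, 5 sampled without mutual overlap:
        # rep overlap counts are Hypergeom(10, 4, 5)
        uni = _slots(10)
        templates = uni[:5]
        target = GenomicElementSet.from_tuples("t", uni[:4])
        n_reps = 10_000
        res = sampled_expected_overlap(templates, uni, target, n_reps=n_reps, seed=4)
        emp = np.bincount(res.counts, minlength=6) / n_reps
        exact = stats.hypergeom.pmf(np.arange(6), 10, 4, 5)
        # KS distance between the two distributions
        ks = np.max(np.abs(np.cumsum(emp) - np.cumsum(exact)))
        assert ks < 0.02
        assert res.expected_mean == pytest.approx(2.0, abs=0.1)

    def test_cpg_matched_sampling(self):
        cpg_index = {"chr1": np.arange(10, 2010, 10)}
        uni = [("chr1", 0, 2000)]
        templates = [Block("chr1", (10, 20, 30, 40), (1.0,) * 3, block_id="b")]
        target = GenomicElementSet.from_tuples("t", [("chr1", 0, 2000)])
        res = sampled_expected_overlap(
            templates, uni, target, n_reps=50, matching="cpg", seed=5, cpg_index=cpg_index
        )
        assert res.observed == 1 and res.p_value == pytest.approx(1.0)

    def test_oversized_template_rejected(self):
        uni = _slots(3, length=50)
        with pytest.raises(ValueError, match="universe"):
            sampled_expected_overlap(
                [("chr1", 0, 500)], uni, GenomicElementSet("t"), n_reps=5, seed=0
            )

    def test_seeded_determinism(self):
        uni = _slots(10)
        target = GenomicElementSet.from_tuples("t", uni[:4])
        a = sampled_expected_overlap(uni[:5], uni, target, n_reps=100, seed=7)
        b = sampled_expected_overlap(uni[:5], uni, target, n_reps=100, seed=7)
        assert np.array_equal(a.counts, b.counts)


class TestMidpointHistogram:
    def test_identical_sets_all_in_first_bin(self):
        blocks = [("chr1", 100, 200), ("chr1", 5000, 5100)]
        hist, excluded = midpoint_distance_histogram(blocks, blocks)
        assert hist[0] == 2 and hist[1:].sum() == 0 and excluded == 0

    def test_single_pair_arithmetic(self):
        hist, excluded = midpoint_distance_histogram(
            [("chr1", 900, 1100)], [("chr1", 1250, 1450)]
        )
        assert hist[3] == 1  # distance 350 -> bin [300, 400)
        assert hist.sum() == 1 and excluded == 0

    def test_conservation_with_exclusions(self):
        a = [("chr1", 0, 10), ("chr1", 100_000, 100_010), ("chr2", 0, 10)]
        b = [("chr1", 40, 60)]
        hist, excluded = midpoint_distance_histogram(a, b)
        assert hist.sum() + excluded == len(a)
        assert excluded == 2  # one beyond 5 kb, one on a B-less chromosome

    def test_translation_invariance(self):
        a = [("chr1", 100, 300), ("chr1", 2000, 2400)]
        b = [("chr1", 700, 900)]
        shift = 12_345
        a2 = [(c, s + shift, e + shift) for c, s, e in a]
        b2 = [(c, s + shift, e + shift) for c, s, e in b]
        h1, e1 = midpoint_distance_histogram(a, b)
        h2, e2 = midpoint_distance_histogram(a2, b2)
        assert np.array_equal(h1, h2) and e1 == e2

    def test_empty_b_excludes_everything(self):
        hist, excluded = midpoint_distance_histogram([("chr1", 0, 10)], [])
        assert hist.sum() == 0 and excluded == 1


class TestEnhancers:
    def _marks(self):
        k4 = GenomicElementSet.from_tuples(
            "H3K4me1",
            [("chr1", 10_000, 10_500), ("chr1", 20_000, 20_500), ("chr1", 30_100, 30_600)],
        )
        k27 = GenomicElementSet.from_tuples("H3K27ac", [("chr1", 10_200, 10_400)])
        return k4, k27

    def test_active_poised_and_proximal_rules(self):
        k4, k27 = self._marks()
        tss = [("chr1", 30_000)]  # 100 bp from the third peak
        calls = classify_enhancers(k4, k27, tss, distal_bp=2000)
        by_start = {c.start: c for c in calls}
        assert by_start[10_000].klass == "active"
        assert by_start[20_000].klass == "poised"
        assert 30_100 not in by_start  # proximal peak dropped

    def test_no_tss_everything_distal(self):
        k4, k27 = self._marks()
        calls = classify_enhancers(k4, k27, [], distal_bp=2000)
        assert len(calls) == 3


class TestBlockComodEnrichment:
    def _blocks(self):
        blocks = []
        for i in range(8):
            start = i * 1000 + 1
            positions = tuple(range(start, start + 50, 10))  # 5 CpGs each
            blocks.append(
                Block("chr1", positions, (1.0,) * 4, block_id=f"b{i}")
            )
        return blocks

    def test_planted_configuration_separates_classes(self):
        blocks = self._blocks()
        classes = {f"b{i}": ("tissue-specific" if i < 4 else "shared-low-MHL") for i in range(8)}
        # co-sites only inside the tissue-specific blocks
        co = {("chr1", p) for b in blocks[:4] for p in b.positions}
        per_block, summary = block_comod_enrichment(blocks, classes, co, n_cpg_genome=1000)
        s = summary.set_index("class")
        assert s.loc["tissue-specific", "fraction_enriched"] == 1.0
        assert s.loc["shared-low-MHL", "fraction_enriched"] == 0.0
        assert s.loc["tissue-specific", "p_value"] < 0.05

    def test_uniform_co_sites_null(self):
        blocks = self._blocks()
        classes = {f"b{i}": ("tissue-specific" if i % 2 else "shared-low-MHL") for i in range(8)}
        co = {("chr1", p) for b in blocks for p in b.positions}
        per_block, summary = block_comod_enrichment(blocks, classes, co, n_cpg_genome=1000)
        fr = summary["fraction_enriched"]
        assert fr.nunique() == 1  # identical enrichment in both classes

    def test_single_class_p_one(self):
        blocks = self._blocks()
        classes = {f"b{i}": "shared-high-MHL" for i in range(8)}
        co = {("chr1", 1)}
        _, summary = block_comod_enrichment(blocks, classes, co, n_cpg_genome=1000)
        assert summary.iloc[0]["p_value"] == pytest.approx(1.0)
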