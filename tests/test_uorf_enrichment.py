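"""Downstream-gene pairing, Fisher exact test, and BH adjustment."""

import math
from math import comb

import numpy as np
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from rappmotif.io_formats import GeneFeature
from rappmotif.uorf_enrichment import (
    GenePair,
    benjamini_hochberg,
    enrichment_table,
    find_downstream,
    fisher_exact,
    group_by_annotation,
    intergenic_distance,
    normalize_annotation,
    pair_uorfs,
    select_uorfs,
)


def feat(fid, start, end, strand, contig="c1", product="", pid=None):
    return GeneFeature(fid, contig, start, end, strand, product, pid or fid)


def make_pair(motif, product_down, uorf_len=100, product_up="hypothetical protein"):
    u = feat("u", 100, 400, "+", product=product_up)
    d = feat("d", 500, 900, "+", product=product_down)
    return GenePair(u, d, motif, uorf_len, 100)


class TestFindDownstream:
    def test_nearest_same_strand_plus(self):
        u = feat("u", 100, 400, "+")
        genes = sorted([u, feat("a", 500, 900, "+"), feat("b", 1500, 1800, "+")],
                       key=lambda f: (f.contig, f.start))
        hit = find_downstream(genes, u)
        assert hit.feature_id == "a"
        assert intergenic_distance(u, hit) == 100

    def test_opposite_strand_excluded(self):
        u = feat("u", 100, 400, "+")
        assert find_downstream([u, feat("a", 500, 900, "-")], u) is None

    def test_minus_strand_translation_direction(self):
        u = feat("u", 1000, 1300, "-")
        genes = [feat("a", 200, 800, "-"), u]
        hit = find_downstream(genes, u)
        assert hit.feature_id == "a"
        assert intergenic_distance(u, hit) == 200

    def test_max_gap_drops_distant(self):
        u = feat("u", 100, 400, "+")
        genes = [u, feat("a", 5000, 5900, "+")]
        assert find_downstream(genes, u, max_gap=1000) is None
        assert find_downstream(genes, u, max_gap=None).feature_id == "a"

    def test_pair_uorfs_agrees_with_naive_search(self, rng):
        # the indexed batch path must match the contract function
        for _ in range(20):
            feats = []
            for i in range(30):
                start = int(rng.integers(1, 50_000))
                end = start + int(rng.integers(50, 2000))
                strand = "+" if rng.random() < 0.5 else "-"
                contig = f"c{int(rng.integers(1, 3))}"
                feats.append(feat(f"f{i}", start, end, strand, contig=contig))
            feats.sort(key=lambda f: (f.contig, f.start))
            motif_map = {f.feature_id: "RAPP" for f in feats[::3]}
            lengths = {f.feature_id: 100 for f in feats}
            pairs = pair_uorfs(feats, motif_map, lengths)
            by_uorf = {p.uorf.feature_id: p.downstream.feature_id for p in pairs}
            for f in feats:
                if f.feature_id not in motif_map:
                    continue
                want = find_downstream(feats, f)
                assert by_uorf.get(f.feature_id) == (want.feature_id if want else None)


class TestSelectAndGroup:
    def test_hypothetical_kept(self):
        pairs = [make_pair("RGPP", "secD")]
        assert select_uorfs(pairs) == pairs

    def test_annotated_uorf_dropped(self):
        pairs = [make_pair("RGPP", "secD", product_up="DNA polymerase")]
        assert select_uorfs(pairs) == []

    def test_hand_filter_of_mixed_fixture(self):
        pairs = [
            make_pair("RGPP", "secD"),                                   # keep
            make_pair("RGPP", "unknown function"),                       # drop: downstream unknown
            make_pair("RGPP", ""),                                       # drop: empty downstream
            make_pair("RGPP", "TonB receptor", product_up="Uncharacterized protein"),  # keep
            make_pair("RGPP", "yidC", product_up="protein of unknown function"),       # keep
            make_pair("RGPP", "ftsZ", product_up="cell division protein"),             # drop: uORF annotated
            make_pair("RGPP", "secA", uorf_len=300),                     # drop: length cap
        ]
        kept = select_uorfs(pairs)
        assert [p.downstream.product_annotation for p in kept] == ["secD", "TonB receptor", "yidC"]

    def test_normalization_merges_case_and_space(self):
        assert normalize_annotation("SecD ") == normalize_annotation("secd")
        assert normalize_annotation("TonB-dependent receptor") != normalize_annotation(
            "TonB dependent receptor"
        )

    def test_group_partition(self):
        pairs = [make_pair("RGPP", a) for a in ["SecD ", "secd", "yidC", "YidC.", "ftsZ"]]
        groups = group_by_annotation(pairs)
        assert {k: len(v) for k, v in groups.items()} == {"secd": 2, "yidc": 2, "ftsz": 1}


# --- exact-integer enumeration oracle for Fisher ---------------------------

def oracle_fisher_two_sided(a, b, c, d):
    """Enumerate all tables with the observed margins using exact integer
    table counts; sum those no more probable than observed (1e-7 slack)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    x_min, x_max = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(x_min, x_max + 1)}
    obs = weights[a]
    total = comb(n, c1)
    acc = sum(w for w in weights.values() if w <= obs * (1 + 1e-7))
    return acc / total


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact(1, 1, 1, 1) == 1.0

    def test_enumeration_example(self):
        # all 5 tables with margins (4,4,4,4): p = 34/70
        assert fisher_exact(3, 1, 1, 3) == pytest.approx(34 / 70, rel=1e-10)

    def test_extreme_table(self):
        assert fisher_exact(0, 10, 10, 0) == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_negative_cell_errors(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 1, 1, 1)

    def test_exhaustive_oracle_total_le_25(self):
        for n in range(1, 26):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = fisher_exact(a, b, c, d)
                        want = oracle_fisher_two_sided(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-9), (a, b, c, d)

    def test_transposition_invariance(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact(a, b, c, d) == pytest.approx(
                fisher_exact(a, c, b, d), rel=1e-9
            )

    def test_agrees_with_scipy_cross_check(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b + c + d == 0:
                continue
            want = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert fisher_exact(a, b, c, d) == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_one_sided_greater(self):
        want = scipy.stats.fisher_exact([[8, 2], [2, 8]], alternative="greater").pvalue
        assert fisher_exact(8, 2, 2, 8, alternative="greater") == pytest.approx(want, rel=1e-9)


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert benjamini_hochberg([0.03]) == [0.03]

    def test_step_up_collapse(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_fixed_point(self):
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_direct_formula_and_statsmodels(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            got = benjamini_hochberg(p)
            # direct step-up formula
            order = np.argsort(p, kind="stable")
            want = np.empty(m)
            for rank_pos, i in enumerate(order, start=1):
                want[i] = min(
                    min(p[j] * m / (list(order).index(j) + 1) for j in order[rank_pos - 1 :]),
                    1.0,
                )
            assert got == pytest.approx(want.tolist(), rel=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            assert got == pytest.approx(sm.tolist(), rel=1e-9)
            assert all(g >= pi for g, pi in zip(got, p))


class TestEnrichmentTable:
    def test_disjoint_groups_infinite_fold(self):
        target = [make_pair("RGPP", "secD") for _ in range(10)]
        control = [make_pair("AGPP", "other gene") for _ in range(10)]
        results = enrichment_table(target, control)
        secd = next(r for r in results if r.group_key == "secd")
        assert (secd.a, secd.b, secd.c, secd.d) == (10, 0, 0, 10)
        assert secd.infinite_fold and math.isinf(secd.fold_enrichment)
        assert secd.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_identical_distributions_null(self):
        target = [make_pair("RGPP", g) for g in ["a", "a", "b", "c"]]
        control = [make_pair("AGPP", g) for g in ["a", "a", "b", "c"]]
        for r in enrichment_table(target, control):
            assert r.fold_enrichment == pytest.approx(1.0)
            assert r.p_value == pytest.approx(1.0)
            assert not r.significant

    def test_margin_sums(self):
        target = [make_pair("RGPP", g) for g in ["a", "b", "b", "c", "d"]]
        control = [make_pair("AGPP", g) for g in ["a", "a", "c"]]
        results = enrichment_table(target, control)
        assert sum(r.a for r in results) == 5
        assert sum(r.c for r in results) == 3

    def test_empty_side_errors(self):
        with pytest.raises(ValueError):
            enrichment_table([], [make_pair("AGPP", "a")])

    def test_planted_five_fold_group_ranks_first(self, rng):
        groups = [f"grp{i}" for i in range(20)]
        n = 300
        probs = np.ones(20)
        probs_t = probs.copy()
        probs_t[3] *= 5.0
        target = [
            make_pair("RGPP", groups[i])
            for i in rng.choice(20, size=n, p=probs_t / probs_t.sum())
        ]
        control = [
            make_pair("AGPP", groups[i]) for i in rng.choice(20, size=n, p=probs / probs.sum())
        ]
        results = enrichment_table(target, control)
        finite = [r for r in results if not r.infinite_fold]
        assert finite[0].group_key == "grp3"
        assert finite[0].significant
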