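"""Frequency-bias statistic against naive enumeration oracles."""

from collections import Counter

import numpy as np
import pytest

from rappmotif.kmer_bias import (
    STANDARD_AA,
    all_patterns,
    bias_table,
    clade_summary,
    composition,
    count_kmers,
    ecdf,
    ecdf_at,
    expected_frequency,
    frequency_bias,
    rank_underrepresented,
    single_genome_report,
    subsample_genomes,
)

from conftest import make_proteome, random_proteome


# --- independent oracle: enumerate every window naively ---------------------

def oracle_windows(proteome, k):
    """All k-windows of standard letters, by direct slicing of every protein."""
    std = set(STANDARD_AA)
    windows = []
    for rec in proteome:
        s = rec.sequence
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= std:
                windows.append(w)
    return windows


def oracle_bias(proteome, pattern):
    k = len(pattern)
    windows = oracle_windows(proteome, k)
    residues = [c for rec in proteome for c in rec.sequence if c in STANDARD_AA]
    tally = Counter(residues)
    exp = 1.0
    for a in pattern:
        exp *= tally[a] / len(residues)
    if not windows or exp == 0:
        return None
    return (windows.count(pattern) / len(windows)) / exp


class TestCountKmers:
    def test_single_window(self):
        counts, total = count_kmers(make_proteome(["RAPP"]), 4)
        assert counts == {"RAPP": 1} and total == 1

    def test_too_short_protein(self):
        counts, total = count_kmers(make_proteome(["MRA"]), 4)
        assert counts == {} and total == 0
        st = frequency_bias(make_proteome(["MRA"]), "RAPP")
        assert st.bias is None and not st.defined

    def test_overlapping_windows_all_count(self, tiny_proteome):
        counts, total = count_kmers(tiny_proteome, 4)
        # hand enumeration: ARAPPA -> ARAP, RAPP, APPA; RAPP -> RAPP
        assert total == 4
        assert counts == {"ARAP": 1, "RAPP": 2, "APPA": 1}

    def test_nonstandard_letters_break_windows(self):
        # X splits ARAPPXRAPP into runs ARAPP (2 windows) and RAPP (1)
        counts, total = count_kmers(make_proteome(["ARAPPXRAPP"]), 4)
        assert total == 3
        assert counts == {"ARAP": 1, "RAPP": 2}


class TestComposition:
    def test_single_letter(self):
        comp = composition(make_proteome(["AAAA"]))
        assert comp[STANDARD_AA.index("A")] == 1.0 and comp.sum() == 1.0

    def test_uniform_four_letters(self):
        comp = composition(make_proteome(["ACDE"]))
        for a in "ACDE":
            assert comp[STANDARD_AA.index(a)] == 0.25

    def test_matches_hand_tally(self, rng):
        prot = random_proteome(rng, 10)
        tally = Counter(c for rec in prot for c in rec.sequence)
        total = sum(tally.values())
        comp = composition(prot)
        for i, a in enumerate(STANDARD_AA):
            assert comp[i] == pytest.approx(tally[a] / total, abs=1e-15)

    def test_no_standard_residue_errors(self):
        with pytest.raises(ValueError, match="standard"):
            composition(make_proteome(["XXXX"]))


class TestExpectedFrequency:
    def test_uniform_closed_form(self):
        comp = np.full(20, 0.05)
        assert expected_frequency("RAPP", comp) == pytest.approx(0.05**4)

    def test_degenerate_composition(self):
        comp = np.zeros(20)
        comp[STANDARD_AA.index("A")] = 1.0
        assert expected_frequency("AAAA", comp) == 1.0

    def test_hand_product(self, rng):
        comp = rng.dirichlet(np.ones(20))
        prod = 1.0
        for a in "RAPP":
            prod *= comp[STANDARD_AA.index(a)]
        assert expected_frequency("RAPP", comp) == pytest.approx(prod, rel=1e-15)

    def test_nonstandard_letter_errors(self):
        with pytest.raises(ValueError, match="X"):
            expected_frequency("RXPP", np.full(20, 0.05))


class TestFrequencyBias:
    def test_degenerate_identity(self):
        st = frequency_bias(make_proteome(["AAAA"]), "AAAA")
        assert (st.observed_freq, st.expected_freq, st.bias) == (1.0, 1.0, 1.0)

    def test_zero_observed_with_positive_expected_is_zero(self):
        st = frequency_bias(make_proteome(["RRRRAAAAPPPP"]), "RAPP")
        assert st.observed_count == 0 and st.bias == 0.0 and st.defined

    def test_oracle_equivalence_random_proteomes(self, rng):
        for _ in range(20):
            prot = random_proteome(rng, int(rng.integers(1, 20)))
            windows = set(oracle_windows(prot, 4))
            probe = list(windows)[:10] + ["RAPP", "WWWW"]
            for pattern in probe:
                got = frequency_bias(prot, pattern)
                want = oracle_bias(prot, pattern)
                if want is None:
                    assert got.bias is None or got.bias == 0.0
                else:
                    assert got.bias == pytest.approx(want, abs=1e-12)

    def test_observed_freqs_sum_to_one(self, rng):
        prot = random_proteome(rng, 15)
        df = bias_table(prot)
        assert df["observed_freq"].sum() == pytest.approx(1.0, abs=1e-12)
        assert df["expected_freq"].sum() == pytest.approx(1.0, abs=1e-9)
        assert len(df) == 160_000

    def test_bias_table_matches_scalar_path(self, rng):
        prot = random_proteome(rng, 5)
        df = bias_table(prot, patterns=["RAPP", "AAAA"])
        for _, row in df.iterrows():
            st = frequency_bias(prot, row["pattern"])
            assert row["observed_count"] == st.observed_count
            if st.defined:
                assert row["bias"] == pytest.approx(st.bias, abs=1e-12)

    def test_per_protein_mode_counts_presence(self):
        prot = make_proteome(["RAPPRAPP", "MRAPPA"])
        df = bias_table(prot, patterns=["RAPP"], per_protein=True)
        assert df["observed_count"].iloc[0] == 2  # two proteins contain it
        df2 = bias_table(prot, patterns=["RAPP"])
        assert df2["observed_count"].iloc[0] == 3  # three windows


class TestSubsample:
    def test_small_clade_kept_whole(self):
        ids = [f"g{i}" for i in range(5)]
        out = subsample_genomes(ids, {g: "A" for g in ids}, cap=1000, seed=1)
        assert out == {"A": sorted(ids)}

    def test_capped_and_deterministic(self):
        ids = [f"g{i:04d}" for i in range(2000)]
        clade = {g: "A" for g in ids}
        a = subsample_genomes(ids, clade, cap=1000, seed=214)
        b = subsample_genomes(ids, clade, cap=1000, seed=214)
        assert a == b and len(a["A"]) == 1000 and len(set(a["A"])) == 1000

    def test_different_seeds_overlap_hypergeometric(self):
        ids = [f"g{i:04d}" for i in range(2000)]
        clade = {g: "A" for g in ids}
        a = set(subsample_genomes(ids, clade, cap=1000, seed=1)["A"])
        b = set(subsample_genomes(ids, clade, cap=1000, seed=2)["A"])
        # E|A∩B| = 1000*1000/2000 = 500, SD ~ 11; allow 5 SD
        assert abs(len(a & b) - 500) < 56


class TestCladeSummary:
    def _stats(self, biases, zeros=None):
        from rappmotif.kmer_bias import PatternStats

        zeros = zeros or [b == 0 for b in biases]
        return [
            PatternStats(f"g{i}", "RAPP", 0 if z else 5, 100, 0.0, 1e-3, b)
            for i, (b, z) in enumerate(zip(biases, zeros))
        ]

    def test_single_genome(self):
        s = clade_summary(self._stats([0.5]), "A")
        assert s.mean_bias == s.median_bias == 0.5
        assert s.fraction_zero == 0.0
        assert s.ecdf_points == [(0.5, 1.0)]

    def test_direct_enumeration(self):
        s = clade_summary(self._stats([0.0, 0.0, 1.0, 1.0]), "A")
        assert s.fraction_zero == 0.5 and s.mean_bias == 0.5
        assert ecdf_at(s.ecdf_points, 0.9) == 0.5
        fracs = [f for _, f in s.ecdf_points]
        assert fracs == sorted(fracs) and fracs[-1] == 1.0

    def test_all_undefined_errors(self):
        from rappmotif.kmer_bias import PatternStats

        stats = [PatternStats("g", "RAPP", 0, 0, 0.0, 0.0, None)]
        with pytest.raises(ValueError, match="undefined"):
            clade_summary(stats, "A")

    def test_null_mean_bias_near_one(self, rng):
        # iid genomes from their own composition: bias of a common pattern ~ 1
        prot = random_proteome(rng, 400, min_len=100, max_len=300, alphabet="ARNDPG")
        st = frequency_bias(prot, "ARND")
        se = 1.0 / np.sqrt(st.total_windows * st.expected_freq)
        assert abs(st.bias - 1.0) < 4 * se


class TestRanking:
    def test_lower_cross_clade_mean_ranks_first(self):
        means = {"c1": {"XXXX": 0.1, "YYYY": 0.5}, "c2": {"XXXX": 0.3, "YYYY": 0.5}}
        ranked = rank_underrepresented(means, top_n=2)
        assert ranked == [("XXXX", pytest.approx(0.2)), ("YYYY", pytest.approx(0.5))]

    def test_tie_break_lexicographic(self):
        means = {"c1": {"BBBB": 0.2, "AAAA": 0.2, "CCCC": 0.2}}
        ranked = rank_underrepresented(means, top_n=3)
        assert [p for p, _ in ranked] == ["AAAA", "BBBB", "CCCC"]

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            rank_underrepresented({"c1": {"AAAA": 0.1}, "c2": {"BBBB": 0.1}})

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_underrepresented({})


class TestSingleGenomeReport:
    def test_report_consistent_with_frequency_bias(self, tiny_proteome):
        df = single_genome_report(tiny_proteome, ["RAPP", "PPAA", "RGPP"])
        row = df[df.motif == "RAPP"].iloc[0]
        st = frequency_bias(tiny_proteome, "RAPP")
        assert row["bias"] == pytest.approx(st.bias)
        assert row["n_proteins"] == 2
        # letters all present but motif absent -> a real zero
        ppaa = df[df.motif == "PPAA"].iloc[0]
        assert ppaa["bias"] == 0.0 and ppaa["n_proteins"] == 0
        # G never occurs -> expected frequency 0 -> bias undefined, not zero
        rgpp = df[df.motif == "RGPP"].iloc[0]
        assert np.isnan(rgpp["bias"])


def test_pattern_universe_size():
    pats = all_patterns(4)
    assert len(pats) == 20**4 == 160_000
    assert len(set(pats)) == 160_000
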