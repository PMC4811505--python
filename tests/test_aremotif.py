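"""ARE scanning, proportion tests and discriminative k-mers."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripscan import (
    UtrSequence,
    build_unbound_control,
    canonicalize,
    classify_are,
    count_pentamers,
    discriminative_kmers,
    gc_content,
    group_are_summary,
    has_consecutive_pentamers,
    max_u_run,
    profile,
    proportion_test,
    shuffle_sequence,
    u_stretch,
)

rna_text = st.text(alphabet="ACGU", max_size=200)


def oracle_pentamers(seq: str) -> int:
    """Sliding-window count of AUUUA over all length-5 windows."""
    return sum(seq[i : i + 5] == "AUUUA" for i in range(len(seq) - 4))


def oracle_max_run(seq: str) -> int:
    runs = re.findall(r"U+", seq)
    return max((len(r) for r in runs), default=0)


class TestCanonicalize:
    def test_dna_and_case_mapped_to_rna(self):
        assert canonicalize("atttaT").sequence == "AUUUAU"
        assert canonicalize("AUUUA").sequence == "AUUUA"

    def test_illegal_character_reports_position(self):
        with pytest.raises(ValueError, match="position 1"):
            canonicalize("AXUUA")

    def test_n_rejected_unless_permitted(self):
        with pytest.raises(ValueError):
            canonicalize("ANU")
        assert canonicalize("ANU", allow_n=True).sequence == "ANU"


class TestPentamerScan:
    @pytest.mark.parametrize(
        "seq,count",
        [
            ("AUUUA", 1),
            ("AUUUAUUUA", 2),  # overlapping occurrences both counted
            ("UAAUUUUUAUGUGUAAUUU", 0),
            ("", 0),
            ("AUUUACAUUUA", 2),
        ],
    )
    def test_counts(self, seq, count):
        assert count_pentamers(seq) == count

    def test_matches_sliding_window_oracle_on_random_sequences(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 2001))
            # AU-heavy composition makes pentamers common
            seq = "".join(rng.choice(list("ACGU"), n, p=[0.4, 0.1, 0.1, 0.4]))
            assert count_pentamers(seq) == oracle_pentamers(seq)

    @pytest.mark.parametrize(
        "seq,expected",
        [("AUUUAUUUA", True), ("AUUUACAUUUA", False), ("", False)],
    )
    def test_consecutive_pentamers(self, seq, expected):
        assert has_consecutive_pentamers(seq) is expected


class TestURun:
    @pytest.mark.parametrize(
        "seq,run,flag",
        [("U" * 17, 17, True), ("U" * 16, 16, False), ("UAUAUA", 1, False), ("", 0, False)],
    )
    def test_boundary(self, seq, run, flag):
        assert max_u_run(seq) == run
        assert u_stretch(seq) is flag

    @settings(max_examples=200, derandomize=True)
    @given(rna_text)
    def test_matches_regex_oracle(self, seq):
        assert max_u_run(seq) == oracle_max_run(seq)


class TestGc:
    @pytest.mark.parametrize(
        "seq,gc", [("GCGC", 1.0), ("AUAU", 0.0), ("UAAUUUUUAUGUGUAAUUU", 2 / 19)]
    )
    def test_values(self, seq, gc):
        assert gc_content(seq) == pytest.approx(gc)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestClassify:
    @pytest.mark.parametrize(
        "count,consec,stretch,cls",
        [
            (2, False, False, "I"),
            (2, True, False, "II"),
            (0, False, True, "III"),
            (0, False, False, "none"),
            (5, False, False, "I"),  # >3 scattered pentamers stay class I
            (3, True, True, "II"),  # precedence II > I > III
            (1, False, True, "I"),
        ],
    )
    def test_classes(self, count, consec, stretch, cls):
        assert classify_are(count, consec, stretch) == cls

    @settings(max_examples=200, derandomize=True)
    @given(rna_text)
    def test_total_function_on_profiles(self, seq):
        p = profile(UtrSequence("x", seq + "A"))  # nonempty
        assert p.are_class in {"I", "II", "III", "none"}
        if p.has_consecutive:
            assert p.pentamer_count >= 2
        assert p.has_u_stretch == (p.max_u_run >= 17)


class TestShuffle:
    @settings(max_examples=100, derandomize=True)
    @given(rna_text.filter(lambda s: len(s) > 0), st.integers(0, 1000))
    def test_composition_and_gc_preserved(self, seq, seed):
        out = shuffle_sequence(seq, seed=seed)
        assert sorted(out) == sorted(seq)
        assert gc_content(out) == gc_content(seq)

    def test_deterministic_and_fixed_point(self):
        assert shuffle_sequence("AAAA", seed=5) == "AAAA"
        s = "AUGCAUGCAUGC"
        assert shuffle_sequence(s, seed=42) == shuffle_sequence(s, seed=42)


class TestUnboundControl:
    def test_sample_excludes_enriched(self):
        expressed = [f"g{i}" for i in range(50)]
        enriched = expressed[:20]
        picked = build_unbound_control(expressed, enriched, 10, seed=0)
        assert len(picked) == 10
        assert not set(picked) & set(enriched)

    def test_whole_complement_and_insufficient_pool(self):
        expressed = ["a", "b", "c"]
        assert set(build_unbound_control(expressed, ["a"], 2, seed=1)) == {"b", "c"}
        with pytest.raises(ValueError):
            build_unbound_control(expressed, expressed, 1)


class TestProportionTest:
    def test_equal_proportions_give_p_one(self):
        res = proportion_test(10, 100, 10, 100)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_symmetry(self):
        a = proportion_test(23, 286, 9, 286)
        b = proportion_test(9, 286, 23, 286)
        assert a.p == pytest.approx(b.p)

    def test_against_exact_permutation_oracle(self, rng):
        # condition on the table margins: permutation null is hypergeometric
        k1, n1, k2, n2 = 23, 286, 9, 286
        res = proportion_test(k1, n1, k2, n2)
        total_k = k1 + k2
        obs_dev = abs(k1 / n1 - k2 / n2)
        hits = 0
        n_perm = 100_000
        labels = np.zeros(n1 + n2, dtype=bool)
        labels[:total_k] = True
        for _ in range(n_perm):
            rng.shuffle(labels)
            p1 = labels[:n1].mean()
            p2 = labels[n1:].mean()
            if abs(p1 - p2) >= obs_dev - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert res.p == pytest.approx(p_perm, abs=0.01)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_test(11, 10, 1, 10)


def hypergeom_tail(k1: int, n1: int, k2: int, n2: int) -> float:
    """P(X >= k1) for X ~ Hypergeom drawing n1 from k1+k2 successes in n1+n2."""
    K, N = k1 + k2, n1 + n2
    denom = math.comb(N, K)
    return sum(
        math.comb(n1, j) * math.comb(n2, K - j) / denom
        for j in range(k1, min(n1, K) + 1)
        if K - j <= n2
    )


class TestDiscriminativeKmers:
    def test_planted_motif_ranked_first(self):
        pos = ["GCGCAUUUAGCGC" + "GC" * 5] * 20
        pos = [p + "ACGU" * i for i, p in enumerate(pos)]
        neg = ["GCGCGCGCGCGCG" + "ACGU" * i for i in range(20)]
        results = discriminative_kmers(pos, neg, e_threshold=1e-3)
        assert results, "no motif found"
        top = results[0]
        assert "AUUUA" in top.motif or top.motif in "GCGCAUUUAGCGC"
        assert any(r.motif == "AUUUA" for r in results)
        auuua = next(r for r in results if r.motif == "AUUUA")
        assert auuua.pos_count == 20 and auuua.neg_count == 0
        assert auuua.e_value < 1e-3

    def test_identical_sets_yield_nothing(self):
        seqs = ["AUGCAUUUAGC", "GGGCCCAAA"]
        assert discriminative_kmers(seqs, list(seqs), e_threshold=0.99) == []

    def test_reverse_run_recovers_gc_motif(self):
        # GC-rich words planted in the negatives: swapping the sets finds them
        au = ["AUAUAUAUAUAUAUAU" + "UA" * i for i in range(15)]
        gc = ["AUAUGGGCCCAUAUAU" + "UA" * i for i in range(15)]
        results = discriminative_kmers(gc, au, e_threshold=1e-2)
        assert results
        # a purely-GC word sits among the maximally discriminative motifs
        best_p = results[0].p
        assert any(set(r.motif) <= {"G", "C"} and r.p == best_p for r in results)

    def test_fisher_p_matches_hypergeometric_tail(self):
        pos = ["AUUUA", "GGGGG", "AUUUA"]
        neg = ["CCCCC", "AUUUA"]
        for r in discriminative_kmers(pos, neg, k_min=5, k_max=5, e_threshold=2e9):
            assert r.p == pytest.approx(
                hypergeom_tail(r.pos_count, 3, r.neg_count, 2), rel=1e-9
            )


class TestGroupSummary:
    def test_identical_groups_all_p_one(self):
        utrs = [canonicalize("AUUUAGCGC" * 5, f"u{i}") for i in range(10)]
        summary = group_are_summary(utrs, list(utrs))
        assert all(t.p == 1.0 for t in summary.tests.values())

    def test_mean_gc_is_plain_average(self):
        a = canonicalize("GCGC", "a")  # gc 1.0
        b = canonicalize("AUAU", "b")  # gc 0.0
        summary = group_are_summary([a, b], [a])
        assert summary.mean_gc["bound"] == pytest.approx(0.5)
        assert summary.mean_gc["control"] == pytest.approx(1.0)

    def test_planted_contrast_detected(self):
        from ripscan import UtrSimConfig, simulate_utrs

        bound, _ = simulate_utrs(
            UtrSimConfig(n_sequences=80, length_range=(400, 600), pentamer_rate=3.0,
                         seed=11, id_prefix="b")
        )
        ctrl, _ = simulate_utrs(
            UtrSimConfig(n_sequences=80, length_range=(400, 600), pentamer_rate=0.0,
                         gc_target=0.46, seed=12, id_prefix="c")
        )
        summary = group_are_summary(
            [canonicalize(s, i) for i, s in bound],
            [canonicalize(s, i) for i, s in ctrl],
        )
        f_bound, f_ctrl = summary.fractions["pentamer"]
        assert f_bound > f_ctrl
        assert summary.tests["pentamer"].p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_are_summary([], [canonicalize("ACGU", "x")])
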