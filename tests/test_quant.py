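"""Exact matching, Karlin–Altschul window, hit filtering, counting, RPKM."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import longest_common_substring
from spliceprobe.gene_model import revcomp
from spliceprobe.quant import (
    AlignmentHit,
    Bait,
    FilterParams,
    ScoringParams,
    compute_rpkm,
    count_junction_reads,
    evalue_length_window,
    exact_match_hits,
    filter_hits,
    junction_ratio,
    karlin_altschul_evalue,
    quantify_sample,
    usage_fractions,
)
from spliceprobe.reads import ReadSet
from spliceprobe.simulate import SimulationConfig, simulate_sample


def random_dna(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestExactMatch:
    def test_read_containing_bait_matches_full_length(self):
        rng = np.random.default_rng(0)
        bait = random_dna(rng, 100)
        read = bait + "A"
        hits = exact_match_hits(bait, [read])
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd[0].match_len == 100
        assert fwd[0].bait_start == 0 and fwd[0].read_start == 0

    def test_reverse_strand_read_matches_same_length(self):
        rng = np.random.default_rng(1)
        bait = random_dna(rng, 100)
        hits = exact_match_hits(bait, [revcomp(bait + "A")])
        best = max(hits, key=lambda h: h.match_len)
        assert best.match_len == 100 and best.strand == "-"

    def test_longest_hit_wins_with_positional_tiebreak(self):
        # two copies of the same 30-mer in the read: smallest read_start wins
        core = "ACGTTGCACCTGA" * 3
        bait = "T" * 30 + core[:30] + "G" * 40
        read = "C" * 10 + core[:30] + "A" * 10 + core[:30] + "C" * 21
        hits = [h for h in exact_match_hits(bait, [read]) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].match_len == 30 and hits[0].read_start == 10

    def test_n_in_bait_rejected_n_in_read_never_matches(self):
        with pytest.raises(ValueError, match="ambiguous"):
            exact_match_hits("ACGTNACGT", ["ACGTACGTA"])
        bait = "ACGTACGTACGTACGTACGT"
        hits = exact_match_hits(bait, [bait[:10] + "N" + bait[11:]])
        best = max(h.match_len for h in hits)
        assert best < 20  # the N splits the match

    @pytest.mark.parametrize("n_pairs,seed", [(120, 3)])
    def test_match_lengths_equal_dp_oracle_on_random_pairs(self, n_pairs, seed):
        rng = np.random.default_rng(seed)
        for _ in range(n_pairs):
            bait = random_dna(rng, 100)
            read = random_dna(rng, 101)
            hits = {h.strand: h for h in exact_match_hits(bait, [read])}
            assert hits.get("+", None) is not None
            assert hits["+"].match_len == longest_common_substring(bait, read)
            assert hits["-"].match_len == longest_common_substring(bait, revcomp(read))


class TestEvalue:
    P = ScoringParams()  # lambda 1.28, K 0.46, reward 1

    def test_formula_values(self):
        e = karlin_altschul_evalue(100, 100, 10**9, self.P)
        assert e == pytest.approx(0.46 * 100 * 1e9 * math.exp(-1.28 * 100))
        assert 4e-60 < e < 4e-23  # inside the default window
        e40 = karlin_altschul_evalue(40, 100, 10**9, self.P)
        assert e40 == pytest.approx(2.7e-12, rel=0.05)
        assert e40 > 4e-23  # rejected by the window

    def test_monotone_in_length_and_database_size(self):
        es = [karlin_altschul_evalue(L, 100, 10**9, self.P) for L in range(10, 100)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert karlin_altschul_evalue(50, 100, 10**10, self.P) > karlin_altschul_evalue(
            50, 100, 10**9, self.P
        )

    def test_window_inversion_matches_forward_scan(self):
        filt = FilterParams()
        lo, hi = evalue_length_window(self.P, filt, m=100, n=10**9)
        assert (lo, hi) == (60, 100)
        inside = [
            L
            for L in range(1, 101)
            if filt.evalue_low
            <= karlin_altschul_evalue(L, 100, 10**9, self.P)
            <= filt.evalue_high
        ]
        assert (min(inside), max(inside)) == (lo, hi)

    def test_degenerate_equal_bounds_window(self):
        e50 = karlin_altschul_evalue(50, 100, 10**9, self.P)
        filt = FilterParams(evalue_low=e50 * 0.999, evalue_high=e50 * 1.001)
        lo, hi = evalue_length_window(self.P, filt, 100, 10**9)
        assert lo == hi == 50

    def test_tenfold_database_shifts_lower_bound_by_ln10_over_lambda(self):
        filt = FilterParams()
        lo1, _ = evalue_length_window(self.P, filt, 100, 10**9)
        lo2, _ = evalue_length_window(self.P, filt, 100, 10**10)
        assert lo2 - lo1 == pytest.approx(math.log(10) / 1.28, abs=1)

    def test_empty_window_is_explicit(self):
        filt = FilterParams(evalue_low=1e-300, evalue_high=2e-300)
        assert evalue_length_window(self.P, filt, 100, 10**9) is None


def _hit(read_id, match_len, bait_start=0, evalue=1e-30, strand="+"):
    return AlignmentHit(read_id, "b", match_len, bait_start, 0, strand, evalue)


class TestFilterAndCount:
    def test_empty_in_empty_out(self):
        res = filter_hits([], FilterParams(), ScoringParams(), n=10**6)
        assert res.hits == [] and not res.truncated

    def test_cap_keeps_smallest_evalues_and_flags_truncation(self):
        filt = FilterParams(max_hits=20_000)
        hits = [_hit(f"r{i}", 70, evalue=4e-30 if i < 4000 else 5e-30)
                for i in range(25_000)]
        res = filter_hits(hits, filt, ScoringParams(), n=10**6)
        assert len(res.hits) == 20_000 and res.truncated
        kept_small = sum(1 for h in res.hits if h.evalue == 4e-30)
        assert kept_small == 4000  # all smaller-E hits retained

    def test_out_of_window_hits_removed(self):
        res = filter_hits(
            [_hit("a", 30, evalue=1e-10), _hit("b", 70, evalue=1e-30)],
            FilterParams(), ScoringParams(), n=10**6,
        )
        assert [h.read_id for h in res.hits] == ["b"]

    def test_junction_anchor_rule(self):
        bait = Bait("J", "A" * 100, junction_offset=50)
        filt = FilterParams(a_min=10)
        # match entirely on the donor side: not junction-spanning
        assert count_junction_reads([_hit("r1", 45, bait_start=0)], bait, filt) == 0
        # spanning offsets 40..99 (10 left / 50 right): counted
        assert count_junction_reads([_hit("r2", 60, bait_start=40)], bait, filt) == 1
        # one-base-short left anchor: rejected
        assert count_junction_reads([_hit("r3", 60, bait_start=41)], bait, filt) == 0
        # same read on both strands counts once
        both = [_hit("r4", 80, bait_start=10), _hit("r4", 80, bait_start=10, strand="-")]
        assert count_junction_reads(both, bait, filt) == 1


class TestRpkm:
    def test_values(self):
        t = compute_rpkm({"a": 0, "b": 50}, {"a": 100, "b": 100}, 10**6)
        assert t.set_index("bait_id").loc["a", "rpkm"] == 0
        assert t.set_index("bait_id").loc["b", "rpkm"] == pytest.approx(500)
        t2 = compute_rpkm({"c": 123}, {"c": 1122}, 25_000_000)
        assert t2["rpkm"].iloc[0] == pytest.approx(123 / (1.122 * 25), rel=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        count=st.integers(0, 10**5),
        blen=st.integers(50, 5000),
        total=st.integers(1000, 10**8),
        factor=st.integers(2, 50),
    )
    def test_scale_invariance(self, count, blen, total, factor):
        base = compute_rpkm({"b": count}, {"b": blen}, total)["rpkm"].iloc[0]
        scaled = compute_rpkm({"b": count * factor}, {"b": blen}, total * factor)[
            "rpkm"
        ].iloc[0]
        halved = compute_rpkm({"b": count}, {"b": blen}, total * 2)["rpkm"].iloc[0]
        assert scaled == pytest.approx(base, rel=1e-9)
        assert halved == pytest.approx(base / 2, rel=1e-9)

    def test_zero_total_reads_fails(self):
        with pytest.raises(ValueError):
            compute_rpkm({"a": 1}, {"a": 100}, 0)


class TestFractionsAndRatios:
    def test_usage_normalization(self):
        assert usage_fractions({"A": 40.0, "B": 35.0, "C": 25.0}) == pytest.approx(
            {"A": 0.40, "B": 0.35, "C": 0.25}
        )
        assert usage_fractions([7.0]) == pytest.approx([1.0])
        assert usage_fractions([0.0, 0.0]) is None  # flagged, not NaN

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=6))
    def test_usage_sums_to_one_when_defined(self, vals):
        frac = usage_fractions(vals)
        if frac is not None:
            assert float(np.sum(frac)) == pytest.approx(1.0)

    def test_junction_ratio(self):
        assert junction_ratio(0.0, 5.0) == 0.0
        assert junction_ratio(3.0, 3.0) == 1.0
        assert junction_ratio(1.0, 0.0) is None


class TestQuantifySample:
    def test_matches_per_bait_reference_route(self, gene, panel, background, profiles):
        """The vectorized sample scanner equals the hit-level route
        (exact_match_hits -> filter_hits -> count_junction_reads) per bait."""
        cfg = SimulationConfig(library_size=4000)
        rs = simulate_sample(gene, background, profiles[0], cfg, 99)
        scoring, filt = ScoringParams(), FilterParams()
        counts, meta = quantify_sample(panel, rs, scoring, filt)
        n = rs.total_nt
        for b in panel:
            window = meta["length_windows"][b.bait_id]
            hits = exact_match_hits(
                b, rs, min_len=window[0], db_size=n, scoring=scoring
            )
            res = filter_hits(hits, filt, scoring, n=n, m=len(b.sequence))
            if getattr(b, "junction_offset", None) is None:
                expected = len({h.read_id for h in res.hits})
            else:
                expected = count_junction_reads(res.hits, b, filt)
            assert counts[b.bait_id] == expected, b.bait_id

    def test_strand_invariance(self, gene, panel, background, profiles):
        cfg = SimulationConfig(library_size=4000)
        rs = simulate_sample(gene, background, profiles[0], cfg, 7)
        counts_fwd, _ = quantify_sample(panel, rs)
        counts_rc, _ = quantify_sample(panel, rs.reverse_complemented())
        assert counts_fwd == counts_rc

    def test_window_soundness(self, gene, panel, background, profiles):
        """Every surviving hit length lies inside the derived length window."""
        from spliceprobe.quant import scan_reads

        cfg = SimulationConfig(library_size=4000)
        rs = simulate_sample(gene, background, profiles[0], cfg, 11)
        scoring, filt = ScoringParams(), FilterParams()
        counts, meta = quantify_sample(panel, rs, scoring, filt)
        for b in panel:
            lo, hi = meta["length_windows"][b.bait_id]
            hits = exact_match_hits(b, rs, min_len=lo, db_size=rs.total_nt)
            res = filter_hits(hits, filt, scoring, n=rs.total_nt, m=len(b.sequence))
            assert all(lo <= h.match_len <= hi for h in res.hits)
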