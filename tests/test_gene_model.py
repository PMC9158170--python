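"""Gene model: transcript enumeration, splicing, baits, ORF/PTC annotation."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from spliceprobe.gene_model import (
    ExonModel,
    GeneModel,
    GeneModelError,
    annotate_orf,
    build_constitutive_bait,
    build_junction_bait,
    complete_spec,
    enumerate_transcripts,
    junction_in_spec,
    revcomp,
    splice_transcript,
)


def toy_gene(lengths=(60, 40), offsets=None, optional=(), name="toy"):
    """Small deterministic gene whose exon i is a run-free pseudo-random string."""
    import random

    rnd = random.Random(17)
    exons = []
    for i, L in enumerate(lengths, start=1):
        seq = "".join(rnd.choice("ACGT") for _ in range(L))
        exons.append(ExonModel(i, seq, (offsets or {}).get(i, {})))
    return GeneModel(name, exons, optional_exons=frozenset(optional))


class TestEnumeration:
    def test_study_event_set_yields_twelve_variants(self, gene):
        specs = enumerate_transcripts(gene, [12, 14, 15])
        assert len(specs) == 12

    def test_empty_event_set_yields_constitutive_transcript(self, gene):
        specs = enumerate_transcripts(gene, [])
        assert len(specs) == 1
        assert all(specs[0].includes(i) for i in (12, 14))

    def test_count_equals_bruteforce_product_of_event_cardinalities(self, gene):
        # brute-force oracle: enumerate the Cartesian product explicitly
        axes = [[True, False], [True, False], list("ABC"), list("AB")]
        expected = len(list(itertools.product(*axes)))
        specs = enumerate_transcripts(gene, [12, 14, 15, 17])
        assert len(specs) == expected == 24
        keys = {
            (s.include[12], s.include[14], s.site_choice[15], s.site_choice[17])
            for s in specs
        }
        assert len(keys) == 24  # deduplicated, all distinct

    def test_deterministic_order(self, gene):
        a = enumerate_transcripts(gene, [12, 14, 15])
        b = enumerate_transcripts(gene, [15, 14, 12])
        assert [s.label() for s in a] == [s.label() for s in b]

    def test_unknown_event_exon_fails_descriptively(self, gene):
        with pytest.raises(GeneModelError, match="neither optional nor multi-acceptor"):
            enumerate_transcripts(gene, [99])


class TestSplicing:
    def test_two_exons_concatenate_with_one_junction(self):
        g = toy_gene((60, 40))
        seq, junctions = splice_transcript(g, complete_spec(g))
        assert len(seq) == 100 and junctions == [60]
        assert seq == g.exon(1).sequence + g.exon(2).sequence

    def test_skipping_middle_exon_joins_flanks(self):
        g = toy_gene((60, 30, 40), optional=(2,))
        seq, junctions = splice_transcript(g, complete_spec(g, {2: False}))
        assert len(seq) == 100 and junctions == [60]
        assert seq == g.exon(1).sequence + g.exon(3).sequence

    def test_acceptor_site_choice_trims_exon_start(self):
        g = toy_gene((60, 60), offsets={2: {"A": 0, "B": 21, "C": 33}})
        seq, _ = splice_transcript(g, complete_spec(g, site_choice={2: "B"}))
        assert len(seq) == 60 + (60 - 21)
        assert seq[60:] == g.exon(2).sequence[21:]

    def test_absent_exon_in_spec_fails(self, gene):
        from spliceprobe.gene_model import TranscriptSpec

        with pytest.raises(GeneModelError):
            splice_transcript(gene, TranscriptSpec(include={99: False}))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(data=st.data())
    def test_transcript_length_identity(self, data):
        """len(transcript) == Σ included exon lengths − Σ chosen site offsets."""
        n = data.draw(st.integers(3, 6))
        lengths = data.draw(
            st.lists(st.integers(40, 80), min_size=n, max_size=n)
        )
        optional = tuple(
            i for i in range(2, n)  # never first/last exon
            if data.draw(st.booleans(), label=f"opt{i}")
        )
        offsets = {}
        for i in range(2, n + 1):
            if data.draw(st.booleans(), label=f"multi{i}"):
                b = data.draw(st.integers(3, 12), label=f"offB{i}")
                offsets[i] = {"A": 0, "B": b}
        g = toy_gene(tuple(lengths), offsets=offsets, optional=optional)
        include = {i: data.draw(st.booleans(), label=f"inc{i}") for i in optional}
        sites = {
            i: data.draw(st.sampled_from(["A", "B"]), label=f"site{i}")
            for i in offsets
        }
        spec = complete_spec(g, include, sites)
        seq, junctions = splice_transcript(g, spec)
        expected = sum(
            len(g.exon(i)) - (offsets.get(i, {"A": 0})[sites.get(i, "A")])
            for i in range(1, n + 1)
            if spec.includes(i)
        )
        assert len(seq) == expected
        assert len(junctions) == sum(spec.includes(i) for i in range(1, n + 1)) - 1


class TestJunctionBaits:
    def test_default_bait_is_100nt_split_50_50(self, gene):
        b = build_junction_bait(gene, 13, 14)
        assert len(b) == 100 and b.junction_offset == 50
        assert b.sequence[:50] == gene.exon(13).sequence[-50:]
        assert b.sequence[50:] == gene.exon(14).sequence[:50]

    def test_tiny_bait_literal(self):
        g = GeneModel("t", [ExonModel(1, "A" * 10), ExonModel(2, "C" * 10)])
        b = build_junction_bait(g, 1, 2, bait_len=10)
        assert b.sequence == "AAAAACCCCC"

    def test_short_acceptor_after_offset_fails_naming_side(self):
        g = GeneModel(
            "t",
            [ExonModel(1, "A" * 60), ExonModel(2, "C" * 34 + "G" * 21, {"A": 0, "B": 21})],
        )
        with pytest.raises(GeneModelError, match="acceptor exon 2 .*34 < 50"):
            build_junction_bait(g, 1, 2, site="B")
        with pytest.raises(GeneModelError, match="donor"):
            build_junction_bait(
                GeneModel("t2", [ExonModel(1, "A" * 10), ExonModel(2, "C" * 60)]), 1, 2
            )

    def test_bait_present_exactly_in_transcripts_using_its_junction(self, gene, panel):
        specs = enumerate_transcripts(gene, [12, 14, 15, 17])
        for b in panel:
            if not hasattr(b, "donor"):
                continue
            for s in specs:
                seq, _ = splice_transcript(gene, s)
                expected = junction_in_spec(gene, s, b.donor, b.acceptor, b.site)
                assert (b.sequence in seq) == expected
                assert revcomp(b.sequence) not in seq


class TestConstitutiveBait:
    def test_fixture_constitutive_block_is_1122_nt(self, gene):
        assert len(build_constitutive_bait(gene, 1, 3)) == 1122

    def test_single_exon_range_is_identity(self, gene):
        assert build_constitutive_bait(gene, 2, 2) == gene.exon(2).sequence

    def test_range_crossing_optional_exon_fails(self, gene):
        with pytest.raises(GeneModelError, match="optional"):
            build_constitutive_bait(gene, 13, 15)


class TestOrfAnnotation:
    def test_full_length_stops_in_last_exon_without_ptc(self, gene):
        ann = annotate_orf(gene, complete_spec(gene))
        assert ann.stop_exon == 17 and not ann.is_ptc and not ann.frame_shifted

    @pytest.mark.parametrize("site", ["A", "B"])
    def test_exon14_skip_with_proximal_sites_creates_exon15_ptc(self, gene, site):
        ann = annotate_orf(gene, complete_spec(gene, {14: False}, {15: site}))
        assert ann.stop_exon == 15 and ann.is_ptc and ann.frame_shifted

    def test_exon14_skip_with_distal_site_reads_through_to_exon17(self, gene):
        ann = annotate_orf(gene, complete_spec(gene, {14: False}, {15: "C"}))
        assert ann.stop_exon == 17 and ann.frame_shifted
        assert not ann.is_ptc  # stop downstream of the last junction

    def test_frame_preserving_exon12_skip(self, gene):
        ann = annotate_orf(gene, complete_spec(gene, {12: False}))
        assert not ann.frame_shifted and ann.stop_exon == 17

    def test_no_stop_reported_as_none(self):
        g = GeneModel("t", [ExonModel(1, "ATG" + "CAC" * 20)])
        assert annotate_orf(g, complete_spec(g)) is None


class TestSerialization:
    def test_json_round_trip(self, gene, tmp_path):
        p = tmp_path / "gene.json"
        gene.to_json(p)
        back = GeneModel.from_json(p)
        assert back == gene

    def test_fasta_exports(self, gene, panel, tmp_path):
        from spliceprobe.gene_model import baits_to_fasta

        gene.exons_to_fasta(tmp_path / "exons.fa")
        baits_to_fasta(panel, tmp_path / "baits.fa")
        text = (tmp_path / "baits.fa").read_text()
        assert ">J13-15A|off=50" in text
        assert ">e1-3\n" in text
        assert ">exon14" in (tmp_path / "exons.fa").read_text()


class TestValidation:
    def test_rejects_bad_alphabet_and_offsets(self):
        with pytest.raises(GeneModelError):
            ExonModel(1, "ACGU")
        with pytest.raises(GeneModelError):
            ExonModel(1, "ACGT" * 10, {"A": 5, "B": 3})
        with pytest.raises(GeneModelError):
            ExonModel(1, "ACGT", {"A": 0, "B": 9})

    def test_rejects_disordered_exons(self):
        with pytest.raises(GeneModelError):
            GeneModel("t", [ExonModel(2, "ACGT"), ExonModel(1, "ACGT")])
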