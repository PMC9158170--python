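"""Build the fixture gene, enumerate its transcripts, and cut junction baits.

The gene mimics an Fmr1-like locus: a 1,122-nt constitutive block (exons 1-3),
two optional exons (12, frame-preserving; 14, frame-shifting when skipped) and
alternative 3' acceptor sites on exon 15 (A/B/C) and exon 17 (A/B).
"""

from spliceprobe import (
    annotate_orf,
    build_constitutive_bait,
    build_junction_bait,
    complete_spec,
    enumerate_transcripts,
    make_gene,
    splice_transcript,
)

gene = make_gene(seed=1)

specs = enumerate_transcripts(gene, [12, 14, 15])
print(f"transcript variants over (exon12, exon14, site15) events: {len(specs)}")

seq, junctions = splice_transcript(gene, complete_spec(gene))
print(f"full-length mRNA: {len(seq)} nt, {len(junctions)} exon-exon junctions")

constitutive = build_constitutive_bait(gene, 1, 3)
print(f"constitutive bait (exons 1-3): {len(constitutive)} nt")

bait = build_junction_bait(gene, 13, 15, site="B")
print(f"{bait.bait_id}: {len(bait)} nt, junction at offset {bait.junction_offset} "
      "(50 nt from each exon)")

# reading-frame consequences of exon-14 skipping
for label, spec in [
    ("full length         ", complete_spec(gene)),
    ("skip exon 14, 15A   ", complete_spec(gene, {14: False}, {15: "A"})),
    ("skip exon 14, 15C   ", complete_spec(gene, {14: False}, {15: "C"})),
]:
    ann = annotate_orf(gene, spec)
    print(f"{label} -> stop on exon {ann.stop_exon}, "
          f"PTC={ann.is_ptc}, frame shifted={ann.frame_shifted}")
# A premature stop >50 nt upstream of the last junction marks the transcript
# as a nonsense-mediated-decay candidate.
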