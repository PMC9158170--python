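# spliceprobe

Junction-bait quantification of alternative splicing across developmental
stages from single-end RNA-seq reads.

## The problem

Alternative splicing of an Fmr1-like gene produces transcript variants that
differ in the inclusion of optional exons (exon 12, frame-preserving; exon 14,
frame-shifting when skipped) and in the choice among alternative 3' splice
acceptor sites (15A/15B/15C on exon 15; 17A/17B on exon 17). Skipping exon 14
shifts the reading frame and creates a premature termination codon (PTC) — on
exon 15 for sites 15A/15B, on exon 17 for 15C — making the skipped transcripts
candidates for nonsense-mediated mRNA decay (NMD). The question is how exon-14
skipping and acceptor-site usage change across brain development.

`spliceprobe` answers it the way a BLAST-against-SRA screen would, but as a
reusable, tested library:

1. **Baits** — for every junction of interest, a 100-nt sequence split 50:50
   across the junction (plus one long constitutive bait, 1,122 nt, as a
   total-abundance reference).
2. **Retrieval** — per sample, every read (both strands) is matched against
   every bait at full identity (maximal mismatch-free common substring, found
   by k-mer seeding with exact run-merging). A hit of length *L* against a
   bait of length *m* in a database of *n* read nucleotides gets a
   Karlin–Altschul E-value, *E = K·m·n·e^(−λL)*, and survives only inside the
   stringency window *E ∈ [4·10⁻⁶⁰, 4·10⁻²³]* and a per-bait cap of 20,000
   hits (smallest E first).
3. **Counting & normalization** — a read supports a junction when its match
   covers the junction point with ≥ 10 matched nt on each side; each read
   counts once per bait. Counts become RPKM:
   `rpkm = count / ((bait_len/1000) · (total_reads/10⁶))`.
4. **Statistics** — samples with anomalously high RPKM on several baits at
   once are excluded (median + 5·MAD on ≥ 3 baits); per bait, stages are
   compared with the tie-corrected Kruskal–Wallis H test (χ², df = k−1; an
   exact permutation option for the tiny per-group n typical here), and
   Dunn's pairwise z tests run only when the omnibus test rejects at α=0.05.
5. **Synthetic study** — a seeded generator builds a fixture gene with the
   structural properties above, a decoy transcriptome, and 13 developmental
   stages (E14…P112) × 4 replicates of 101-nt unpaired reads, so the entire
   pipeline is exercised and validated end to end without any download.

## Worked example

```python
from spliceprobe import RunConfig, SimulationConfig, run_pipeline

config = RunConfig(seed=1, sim=SimulationConfig(library_size=20_000, replicates=2))
summary = run_pipeline(config, out_dir="run")
d = summary.stats_digest["J13-14"]
print(d["H"], d["df"], d["p"])
```

Running the full default study instead (`RunConfig(seed=1)`: 13 stages ×
4 replicates × 2×10⁵ reads, ~2 min on one CPU) prints, for the exon-14
inclusion junction 13–14:

```
H = 42.36, df = 12, p = 2.9e-05, Dunn run
```

i.e. 13–14 junction abundance differs strongly across stages; Dunn's post-hoc
flags all four elevated-skipping stages (E17–E20, simulated skip fraction
0.45) against E14 (baseline 0.10). The run recovers the simulated splicing
state from reads alone: pooled skip estimates 0.466 / 0.111 for the two
levels, acceptor-site-15 usage 40.2% / 34.9% / 24.9% against the simulated
40/35/25, and a 13–15C/10–11 RPKM ratio of ~3% at late postnatal stages (the
low-percent regime expected when skipped transcripts are rare).

Smaller, capability-by-capability scripts live in `examples/`:
gene models and ORF/PTC annotation (`01`), read simulation against the
closed-form junction-count expectation (`02`), exact matching and the
E-value→match-length window (`03`), outlier exclusion and stage statistics
(`04`), the full pipeline plus plots (`05`).

A thin CLI wraps the same library calls:

```bash
spliceprobe simulate --out sim/                 # FASTQ + sample sheet + baits
spliceprobe quantify --baits sim/baits.fa --samples sim/samples.tsv --out rpkm.tsv
spliceprobe stats --rpkm rpkm.tsv --out stats/
spliceprobe run --seed 1 --out run/             # everything, from one config
spliceprobe report --run-dir run/               # plots + text digest
```

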