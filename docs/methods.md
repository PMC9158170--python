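# Methods

## Scope and model

`spliceprobe` quantifies alternative splicing of one focal multi-exon gene
from bulk, single-end RNA-seq, using exact-match retrieval of junction-bait
sequences — the in-silico analogue of BLASTing short junction probes against a
read archive. It does not align reads to a genome; everything rests on exact
substring identity between reads and baits, which is what makes the
Karlin–Altschul statistics and the closed-form count expectations exact.

The gene model is an ordered exon list. Two event types generate transcript
diversity: optional exons (included or skipped) and multi-acceptor exons
(several 3' splice acceptor sites, each an offset into the exon where the
retained part begins). A transcript spec assigns one outcome per event; the
spliced mRNA is the concatenation of the retained exon parts. For the default
study events — exon 12 in/out, exon 14 in/out, site 15 ∈ {A,B,C},
site 17 ∈ {A,B} — that is 24 specs (12 over the commonly reported
exon-12/exon-14/site-15 events).

### ORF and PTC annotation

Translation is scanned codon-by-codon from the annotated start. The stop is
classified as a premature termination codon (PTC) when its 3' end lies more
than `ejc_rule_nt` nucleotides upstream of the transcript's last exon–exon
junction — the standard exon-junction-complex model of NMD triggering. The
rule length is a parameter (default 50 nt); any stop within the last exon is
never a PTC. `frame_shifted` reports whether the removed sequence (skipped
exons, trimmed acceptor offsets) upstream of the stop is not a multiple of 3.
When no in-frame stop exists the annotation is `None` rather than an error.

## The fixture gene

Real sequences are not packaged; a deterministic fixture gene reproduces the
structural facts that matter:

* exon labels {1,2,3} form a 1,122-nt constitutive block (300+400+422), the
  long reference bait;
* exons {10..17} carry the junction panel; exon 14 (151 nt, not a multiple of
  3) shifts the frame when skipped; exon 12 (150 nt) does not;
* acceptor offsets 15A/B/C = 0/21/33 and 17A/B = 0/30 are congruent mod 3, so
  site choice alone never changes the frame.

Sequences are drawn under a *no-stop-in-any-frame* constraint: a T is never
followed by A or G (every stop codon begins TA or TG), and every exon and
acceptor site begins with C so no stop can straddle a junction in any reading
phase. Three stop codons are then inserted at arithmetically determined
positions: the natural stop near the end of exon 17 (in the frame of
exon-14-containing transcripts), a PTC in exon 15 between offsets B and C (in
the skip-14 frame, hence hit by 15A and 15B but excised by 15C), and a stop
early in exon 17 in the skip-14 frame (the termination point of skip-14+15C
transcripts). By construction these are the only stops any enumerated
transcript encounters; the builder verifies the resulting ORF facts and the
uniqueness of every bait across all 24 transcripts and the decoy set (both
strands), re-drawing deterministically on the (never observed in practice)
chance of a collision.

## Read simulation

Per read: the focal gene is chosen with probability `target_fraction`,
otherwise a uniformly chosen decoy; focal reads sample a transcript spec from
the stage profile (exon-12 inclusion, exon-14 skip, site-15 and site-17
usage), a uniform start over valid positions, and a uniform strand. Errors are
i.i.d. substitutions (default rate 0, since full-identity filtering turns
errors into pure count deflation; the option exists for robustness
experiments). Quality strings are constant; there is no positional or GC bias
and no indel model — the analysis consumes only exact identity, so these
nuisances would only rescale counts. Decoys are uniform random sequence: only
their total read mass (the RPKM denominator) and non-collision with baits
matter, not their composition. Consequently, passing tests demonstrate
correctness of the counting machinery and the statistical pipeline under the
stated model, not robustness to real-library artefacts (coverage bias,
adapter contamination, multimapping paralogs).

The expected junction-spanning count for a transcript class of length L is

```
E[count] = N_t · (R − 2·a_min + 1) / (L − R + 1)
```

with R the read length, `a_min` the per-side anchor, and N_t the expected
number of reads from that class; mixtures (e.g. exon-12 in/out) are summed
per class. This closed form is the simulator's calibration oracle: observed
counts fall within 3 Poisson σ of it in ≈99% of replicate×junction cases.

### Default study conditions

13 forebrain stages E14…P112, 4 replicates, 2×10⁵ reads of 101 nt per sample
(a desk-scale library size chosen for runtime; depth only scales counting
noise). Exon-14 skip fraction 0.45 on E17–E20 versus 0.10 elsewhere; site-15
usage 0.40/0.35/0.25; site 17B constitutive (17A usage 0, so the 16–17A bait
retrieves nothing — a built-in negative control); exon-12 inclusion 0.7.
Total focal abundance declines shallowly from 1.2% of the library (E14) to
0.65% (P112) with a bump at P3: a modest, monotone developmental decline
whose shape leaves exon-14 skipping, not total abundance, as the dominant
contrast in the elevated window. Per-sample seeds derive from the global seed
by stable hashing of the sample id, so adding samples never perturbs others.

## Retrieval and counting

Baits: per junction, the donor's last 50 nt + the acceptor's first 50 nt
counted from the chosen site offset (the 50:50 rule; bait length
configurable); plus the 1,122-nt constitutive bait.

Matching: maximal mismatch-free common substrings, both strands. All k-mer
matches (default seed 16) between bait panel and reads are found by hashed
lookup; a run of c consecutive k-mer matches on one diagonal *is* a maximal
common substring of length c+k−1, so no extension step is needed and results
are exact for all matches ≥ k. The public per-bait API cascades halving seed
sizes for reads without a hit, making reported lengths equal the
dynamic-programming longest-common-substring value down to a configurable
minimum. Full identity is interpreted per local match (no mismatches inside
the reported match), matching per-HSP identity semantics rather than
full-bait coverage; forcing L = bait length via the E-window recovers the
stricter reading.

Filtering: E = K·m·n·e^(−λ·reward·L) with defaults λ=1.28, K=0.46, reward=1
(ungapped nucleotide-BLAST-like +1/−2 scoring); n is the sample's total read
nucleotides. The E window [4e-60, 4e-23] is inverted to an integer
match-length window per bait and sample, with the closed-form inversion
verified against the forward formula at the boundaries (floating-point safe).
At the study's scales the window is ≈[56..59, 100], comfortably below the
minimum 60-nt match implied by a junction-spanning read with 10-nt anchors —
so the window never costs true junction reads while discarding chance
matches. The 20,000-hit cap retains smallest E first (ties by read order) and
flags truncation. Counting: one count per read per bait; junction baits
additionally require the match to cover the junction with ≥ `a_min` = 10 nt
per side (the anchor parameter is this artifact's explicit operationalization
of "junction-spanning"). RPKM uses the bait length and the sample's total
read count.

## Statistics

Outliers: within each (structure, stage) group, a sample is excluded when its
RPKM exceeds the group median + c·MAD (raw MAD, c = 5) for ≥ 3 distinct
baits — a reproducible operationalization of "too much input RNA inflates
every target at once". Both parameters are exposed; groups of < 3 samples are
skipped with a note. With identical replicate values MAD is 0 and the strict
inequality keeps equal values unflagged.

Stage comparison: tie-corrected Kruskal–Wallis
H = [12/(N(N+1)) Σ R²ᵢ/nᵢ − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)], p from χ² with
k−1 df by default. At this study's group sizes (n ≈ 4, k = 13) the χ²
approximation is conservative (measured ≈2% type-I at nominal 5% over 1000
null replicates), so a permutation method is provided and recommended for
small n: because ranking is permutation-invariant and the tie pattern of the
pooled sample is fixed, the null is built by permuting the midranks directly
(vectorized; seeded; ≈5% type-I at nominal 5%). The χ² default mirrors the
conventional procedure for the headline comparisons.

Dunn's post-hoc: zᵢⱼ = (R̄ᵢ−R̄ⱼ)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)],
two-sided normal p, run for all k(k−1)/2 pairs but only when the omnibus test
rejects at α (gatekeeping). Adjustment is `none` by default (classical Dunn at
per-pair α = 0.05); Bonferroni and Holm are options — with 78 pairs at k=13,
unadjusted flags should be read as exploratory.

## Numerical conventions and degenerate inputs

0-based, half-open coordinates internally; 1-based exon labels for display.
Site labels are ordered text labels, not hard-coded names. Deterministic
orderings everywhere (event enumeration lexicographic; hit ties by smallest
bait then read offset; cap ties by read order). Usage fractions of an all-zero
sibling set are `None` (flagged), never NaN; ratios with zero denominator
likewise. Floats in tables are written with `%.10g`, making re-runs
byte-identical. All randomness flows from numpy `default_rng` seeds derived
from one global seed.

## Limitations

* Exact matching only: no mismatch tolerance, gaps, or quality awareness; a
  nonzero error rate deflates counts by ≈(1−e)^R rather than being modeled.
* The E-value window's correspondence to any particular BLAST service
  configuration is approximate by construction (scoring flavor and effective
  database length conventions differ between deployments).
* The decoy transcriptome is random sequence; results say nothing about
  cross-hybridization with real paralogs.
* Stage profiles beyond the anchored values (13 stages, 4 replicates, 40%
  site-A usage, 0.45/0.10 skip levels) are plausible defaults, not estimates.
* Protein-level consequences (isoform deduplication, domain structure) are
  out of scope; the ORF annotation stops at PTC/frame classification.
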