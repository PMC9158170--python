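"""Seeded synthetic study: fixture gene, decoy transcriptome, stage-wise read sets.

This module builds everything needed to exercise the quantification pipeline
without external data, emulating a developmental brain RNA-seq design:
13 stages (E14..P112), ~4 replicates per stage, unpaired 101-nt reads, a focal
multi-exon gene with an optional exon (14) whose skipping shifts the reading
frame, a second optional exon (12) that preserves frame, three alternative
acceptor sites on exon 15 and two on exon 17, over a background of decoy
transcripts supplying the RPKM denominator.

The fixture gene is constructed, not sampled blindly: exon sequences are drawn
under a no-stop-in-any-frame constraint (a T is never followed by A or G, and
every exon and acceptor site begins with C so no stop can straddle a junction),
then three stop codons are inserted at arithmetically chosen phases so that

* the full-length transcript terminates in the last exon (17),
* skipping exon 14 with acceptor site 15A or 15B truncates on exon 15
  (a premature termination codon, an NMD candidate),
* skipping exon 14 with site 15C reads through to a stop on exon 17.

Every junction bait is then verified to occur exactly once in each transcript
carrying its junction, and never elsewhere (including the decoys and both
strands); failures trigger deterministic re-drawing.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gene_model import (
    ExonModel,
    GeneModel,
    GeneModelError,
    TranscriptSpec,
    annotate_orf,
    build_constitutive_bait,
    build_junction_bait,
    enumerate_transcripts,
    junction_in_spec,
    revcomp,
    splice_transcript,
)
from .quant import Bait
from .reads import ReadSet, encode_seq, revcomp_codes

FOREBRAIN_STAGES = [
    "E14", "E15", "E16", "E17", "E18", "E19", "E20",
    "P0", "P3", "P7", "P14", "P42", "P112",
]

#: junction panel quantified by default (donor exon, acceptor exon, site)
DEFAULT_JUNCTIONS: list[tuple[int, int, str | None]] = [
    (10, 11, None),
    (13, 14, None),
    (14, 15, "A"), (14, 15, "B"), (14, 15, "C"),
    (13, 15, "A"), (13, 15, "B"), (13, 15, "C"),
    (16, 17, "A"), (16, 17, "B"),
]


@dataclass(frozen=True)
class StageProfile:
    """Ground-truth splicing state of one developmental stage."""

    stage_label: str
    target_fraction: float
    skip_fraction: float
    site15_usage: Mapping[str, float]
    site17_usage: Mapping[str, float]
    exon12_fraction: float = 0.7
    structure: str = "forebrain"

    def __post_init__(self) -> None:
        if not (0 < self.target_fraction < 1):
            raise ValueError("target_fraction must lie in (0, 1)")
        for name, v in [("skip_fraction", self.skip_fraction),
                        ("exon12_fraction", self.exon12_fraction)]:
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, vec in [("site15_usage", self.site15_usage),
                          ("site17_usage", self.site17_usage)]:
            vals = list(vec.values())
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector summing to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-design parameters shared by all samples."""

    read_length: int = 101
    library_size: int = 200_000
    error_rate: float = 0.0
    replicates: int = 4
    seed: int = 0
    background_n: int = 20
    background_len: int = 1500

    def __post_init__(self) -> None:
        if self.library_size <= 0 or self.read_length < 2:
            raise ValueError("library_size and read_length must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# fixture gene construction
# ---------------------------------------------------------------------------

_DEFAULT_EXON_LENGTHS = {
    1: 300, 2: 400, 3: 422,          # constitutive block (sums to 1,122 nt)
    10: 150, 11: 150, 12: 150, 13: 150,
    14: 151,                          # not a multiple of 3: skipping shifts frame
    15: 201, 16: 150, 17: 171,
}
_DEFAULT_SITE_OFFSETS = {15: {"A": 0, "B": 21, "C": 33}, 17: {"A": 0, "B": 30}}
_DEFAULT_OPTIONAL = frozenset({12, 14})


def _draw_nostop(rng: np.random.Generator, length: int, head: str = "C") -> list[str]:
    """Random DNA with no stop codon in any reading frame.

    Enforced locally: T is never followed by A or G (every stop starts TA/TG),
    and the sequence begins with ``head``.
    """
    seq = list(head)
    for _ in range(length - len(head)):
        if seq[-1] == "T":
            seq.append("CT"[rng.integers(2)])
        else:
            seq.append("ACGT"[rng.integers(4)])
    return seq


def _insert_stop(seq: list[str], pos: int) -> None:
    seq[pos : pos + 3] = list("TAA")


def default_bait_panel(
    model: GeneModel,
    bait_len: int = 100,
    junctions: Sequence[tuple[int, int, str | None]] | None = None,
    constitutive_range: tuple[int, int] = (1, 3),
):
    """The study's retrieval targets: one long constitutive bait + junction baits."""
    first, last = constitutive_range
    panel = [Bait(f"e{first}-{last}", build_constitutive_bait(model, first, last))]
    for d, a, s in (junctions if junctions is not None else DEFAULT_JUNCTIONS):
        panel.append(build_junction_bait(model, d, a, s, bait_len))
    return panel


def validate_bait_uniqueness(
    model: GeneModel,
    baits: Sequence,
    background: Sequence[str] = (),
    events: Sequence[int] = (12, 14, 15, 17),
) -> None:
    """Each junction bait must occur exactly once per transcript carrying its
    junction, never in other transcripts, decoys, or on the reverse strand."""
    specs = enumerate_transcripts(model, events)
    tx = [splice_transcript(model, s)[0] for s in specs]
    for b in baits:
        junctional = getattr(b, "junction_offset", None) is not None and hasattr(b, "donor")
        for s, t in zip(specs, tx):
            expected = (
                1 if not junctional
                else int(junction_in_spec(model, s, b.donor, b.acceptor, b.site))
            )
            if t.count(b.sequence) != expected:
                raise GeneModelError(
                    f"bait {b.bait_id}: {t.count(b.sequence)} occurrences in "
                    f"{s.label()}, expected {expected}"
                )
            if revcomp(b.sequence) in t:
                raise GeneModelError(f"bait {b.bait_id}: reverse-strand collision")
        for i, d in enumerate(background):
            if b.sequence in d or revcomp(b.sequence) in d:
                raise GeneModelError(f"bait {b.bait_id}: collision with decoy {i}")


def _orf_expectations(model: GeneModel) -> None:
    """Assert the designed stop-placement facts hold on the built gene."""
    full = annotate_orf(model, _spec(model, include14=True, site15="A"))
    assert full is not None and full.stop_exon == 17 and not full.is_ptc
    for site in ("A", "B"):
        ann = annotate_orf(model, _spec(model, include14=False, site15=site))
        assert ann is not None and ann.stop_exon == 15 and ann.is_ptc and ann.frame_shifted
    ann_c = annotate_orf(model, _spec(model, include14=False, site15="C"))
    assert ann_c is not None and ann_c.stop_exon == 17 and ann_c.frame_shifted


def _spec(model: GeneModel, include14: bool, site15: str,
          include12: bool = True, site17: str = "B") -> TranscriptSpec:
    from .gene_model import complete_spec
    return complete_spec(
        model, {12: include12, 14: include14}, {15: site15, 17: site17}
    )


def make_gene(
    seed: int,
    exon_lengths: Mapping[int, int] | None = None,
    site_offsets: Mapping[int, Mapping[str, int]] | None = None,
    optional_exons: frozenset[int] = _DEFAULT_OPTIONAL,
    name: str = "fixgene",
    max_tries: int = 25,
) -> GeneModel:
    """Deterministic fixture gene with the study's structural properties.

    Exon labels {1,2,3} form the 1,122-nt constitutive block; {10..17} carry the
    junction panel.  Stop codons are placed so that skipping exon 14 with
    acceptor 15A/15B truncates on exon 15 while 15C reads through to exon 17;
    the full-length ORF ends in exon 17.  Custom ``exon_lengths`` must keep
    exon 14's length indivisible by 3 and acceptor offsets congruent mod 3.
    """
    lengths = dict(exon_lengths or _DEFAULT_EXON_LENGTHS)
    offsets = {k: dict(v) for k, v in (site_offsets or _DEFAULT_SITE_OFFSETS).items()}
    if 14 in lengths and lengths[14] % 3 == 0:
        raise GeneModelError("exon 14 length must not be a multiple of 3")
    rng = np.random.default_rng(int(seed))

    order = sorted(lengths)
    for attempt in range(max_tries):
        seqs: dict[int, list[str]] = {}
        for idx in order:
            s = _draw_nostop(rng, lengths[idx])
            for off in offsets.get(idx, {}).values():
                if off > 0:
                    s[off] = "C"  # acceptor entry: no stop may straddle the junction
            seqs[idx] = s
        seqs[order[0]][0:3] = list("ATG")  # translation start at exon 1, offset 0

        # phase arithmetic for the three designed stops (all positions 0-based)
        up15 = sum(lengths[i] for i in order if i < 15)          # exon-15 entry, skip-14
        u15 = up15 - lengths[14]
        q = next(p for p in range(22, offsets[15]["C"] - 2)
                 if (u15 + p) % 3 == 0)                           # PTC shared by 15A/15B
        _insert_stop(seqs[15], q)
        u17c = u15 + (lengths[15] - offsets[15]["C"]) + lengths[16]
        z2 = next(p for p in range(offsets[17]["B"] + 3, lengths[17] - 3)
                  if (u17c + p) % 3 == 0)                         # stop for skip-14+15C
        _insert_stop(seqs[17], z2)
        u17 = up15 + lengths[15] + lengths[16]
        z0 = next(p for p in range(lengths[17] - 24, z2 + 3, -1)
                  if (u17 + p) % 3 == 0)                          # natural stop
        _insert_stop(seqs[17], z0)

        model = GeneModel(
            name=name,
            exons=[
                ExonModel(i, "".join(seqs[i]), offsets.get(i, {})) for i in order
            ],
            optional_exons=optional_exons,
            start_codon=(order[0], 0),
        )
        try:
            _orf_expectations(model)
            validate_bait_uniqueness(model, default_bait_panel(model))
        except (AssertionError, GeneModelError):
            continue  # re-draw deterministically from the same stream
        return model
    raise GeneModelError(
        f"could not build a valid fixture gene in {max_tries} draws; "
        "use longer exons"
    )


def make_background(
    seed: int, n: int, length: int, baits: Sequence = (), max_tries: int = 25
) -> list[str]:
    """Seeded decoy transcripts, guaranteed free of bait substrings (both strands)."""
    rng = np.random.default_rng(int(seed))
    decoys = []
    for _ in range(n):
        for _try in range(max_tries):
            s = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
            if all(b.sequence not in s and revcomp(b.sequence) not in s for b in baits):
                decoys.append(s)
                break
        else:
            raise GeneModelError("could not draw a bait-free decoy transcript")
    return decoys


# ---------------------------------------------------------------------------
# stage profiles and read simulation
# ---------------------------------------------------------------------------

def default_study_profiles() -> list[StageProfile]:
    """The 13 forebrain stages with the study's splicing anchors.

    Total focal-gene abundance declines shallowly across development with a
    bump at P3; exon-14 skipping is elevated (0.45 vs 0.10) in the late
    embryonic window E17–E20; acceptor-site 15A carries 40% of 14–15 junctions;
    site 17B is effectively constitutive (17A unused).
    """
    target = [0.012, 0.0115, 0.011, 0.0105, 0.010, 0.0095, 0.009,
              0.0085, 0.0105, 0.008, 0.0075, 0.007, 0.0065]
    elevated = {"E17", "E18", "E19", "E20"}
    return [
        StageProfile(
            stage_label=stage,
            structure="forebrain",
            target_fraction=tf,
            skip_fraction=0.45 if stage in elevated else 0.10,
            site15_usage={"A": 0.40, "B": 0.35, "C": 0.25},
            site17_usage={"A": 0.0, "B": 1.0},
            exon12_fraction=0.7,
        )
        for stage, tf in zip(FOREBRAIN_STAGES, target)
    ]


def spec_probabilities(
    model: GeneModel, profile: StageProfile
) -> tuple[list[TranscriptSpec], np.ndarray]:
    """All focal transcript specs with their sampling probabilities."""
    specs = enumerate_transcripts(model, [12, 14, 15, 17])
    probs = []
    for s in specs:
        p = profile.exon12_fraction if s.includes(12) else 1 - profile.exon12_fraction
        p *= (1 - profile.skip_fraction) if s.includes(14) else profile.skip_fraction
        p *= profile.site15_usage[s.site(15)]
        p *= profile.site17_usage[s.site(17)]
        probs.append(p)
    probs = np.asarray(probs, dtype=float)
    return specs, probs / probs.sum()


def class_probability(
    profile: StageProfile, donor: int, acceptor: int, site: str | None = None
) -> float:
    """Probability that a focal transcript carries the given junction."""
    p = 1.0
    if donor == 12 or acceptor == 12:
        p *= profile.exon12_fraction
    if (donor, acceptor) == (11, 13):
        p *= 1 - profile.exon12_fraction
    if donor == 14 or acceptor == 14:
        p *= 1 - profile.skip_fraction
    if (donor, acceptor) == (13, 15):
        p *= profile.skip_fraction
    if acceptor == 15:
        p *= profile.site15_usage[site]
    if acceptor == 17:
        p *= profile.site17_usage[site]
    return p


def expected_junction_reads(
    profile: StageProfile,
    config: SimulationConfig,
    junction: tuple[int, int, str | None],
    transcript_len: int,
    a_min: int,
) -> float:
    """Closed-form expected junction-spanning read count for one transcript class.

    ``N_t · (R − 2·a_min + 1)/(L − R + 1)`` with ``N_t`` the expected number of
    reads drawn from transcripts carrying the junction, R the read length and L
    the transcript length; a positive error rate deflates the expectation by at
    most ``(1 − e)^R`` (every substitution breaks full identity).
    """
    R = config.read_length
    if R < 2 * a_min or transcript_len < R:
        raise ValueError("need read_length >= 2*a_min and transcript_len >= read_length")
    d, a, s = junction
    n_t = config.library_size * profile.target_fraction * class_probability(profile, d, a, s)
    expected = n_t * (R - 2 * a_min + 1) / (transcript_len - R + 1)
    if config.error_rate > 0:
        expected *= (1 - config.error_rate) ** R
    return expected


def expected_junction_reads_exact(
    model: GeneModel,
    profile: StageProfile,
    config: SimulationConfig,
    junction: tuple[int, int, str | None],
    a_min: int,
) -> float:
    """Expectation summed over every transcript class carrying the junction
    (accounts for length differences between exon-12 in/out variants etc.)."""
    d, a, s = junction
    specs, probs = spec_probabilities(model, profile)
    total = 0.0
    R = config.read_length
    for spec, p in zip(specs, probs):
        if not junction_in_spec(model, spec, d, a, s):
            continue
        L = len(splice_transcript(model, spec)[0])
        n_t = config.library_size * profile.target_fraction * p
        total += n_t * (R - 2 * a_min + 1) / (L - R + 1)
    if config.error_rate > 0:
        total *= (1 - config.error_rate) ** R
    return total


def derive_sample_seed(global_seed: int, sample_id: str) -> int:
    """Stable per-sample seed: adding a sample never perturbs the others."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(sample_id.encode())) % (2**31)


def simulate_sample(
    gene: GeneModel,
    background: Sequence[str],
    profile: StageProfile,
    config: SimulationConfig,
    sample_seed: int,
    sample_id: str | None = None,
) -> ReadSet:
    """One sample's single-end reads, bit-identical for a fixed seed.

    Per read: focal gene with probability ``target_fraction`` (transcript class
    sampled from the profile) else a uniform decoy; uniform start over valid
    positions; strand uniform; optional per-base substitution errors.
    """
    rng = np.random.default_rng(int(sample_seed))
    specs, probs = spec_probabilities(gene, profile)
    focal = [encode_seq(splice_transcript(gene, s)[0]) for s in specs]
    decoys = [encode_seq(b) for b in background]

    R = config.read_length
    keep_f = [i for i, t in enumerate(focal) if t.size >= R]
    if len(keep_f) < len(focal):
        warnings.warn(
            f"{len(focal) - len(keep_f)} focal transcript(s) shorter than the "
            f"read length were excluded from simulation"
        )
        probs = probs[keep_f] / probs[keep_f].sum()
        focal = [focal[i] for i in keep_f]
    keep_b = [d for d in decoys if d.size >= R]
    if len(keep_b) < len(decoys):
        warnings.warn(
            f"{len(decoys) - len(keep_b)} decoy transcript(s) shorter than the "
            f"read length were excluded from simulation"
        )
    sources = focal + keep_b
    if not keep_b:
        raise ValueError("no usable background transcript")
    lens = np.array([t.size for t in sources], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])[:-1]
    concat = np.concatenate(sources)
    windows = np.lib.stride_tricks.sliding_window_view(concat, R)

    n = config.library_size
    is_focal = rng.random(n) < profile.target_fraction
    src = np.empty(n, dtype=np.int64)
    nf = int(is_focal.sum())
    src[is_focal] = rng.choice(len(focal), size=nf, p=probs)
    src[~is_focal] = len(focal) + rng.integers(0, len(keep_b), size=n - nf)
    starts = np.floor(rng.random(n) * (lens[src] - R + 1)).astype(np.int64)
    codes = windows[offsets[src] + starts].copy()

    flip = rng.random(n) < 0.5
    codes[flip] = revcomp_codes(codes[flip])
    if config.error_rate > 0:
        err = rng.random(codes.shape) < config.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.int64)
        codes[err] = ((codes[err].astype(np.int64) + shift) % 4).astype(np.uint8)
    return ReadSet(codes, sample_id=sample_id or f"{profile.structure}_{profile.stage_label}")
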