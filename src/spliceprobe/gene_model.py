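"""Exon-level gene models, transcript enumeration, splicing and bait construction.

The central object is a :class:`GeneModel`: an ordered list of exons, a subset of
which are *optional* (may be skipped by alternative splicing) and some of which
carry several alternative 3' splice acceptor sites (labelled ``"A" < "B" < "C"``,
each an offset into the exon at which the retained portion begins).  From a model
and a :class:`TranscriptSpec` (one inclusion decision per optional exon, one site
choice per multi-acceptor exon) the spliced mRNA sequence is obtained by
concatenation, and junction *baits* — fixed-length sequences centred on an
exon–exon junction, half from the donor exon and half from the acceptor — are cut
out for exact-match read retrieval.

Coordinates are 0-based and half-open internally; exon ``index`` keeps the
conventional 1-based biological numbering for display.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DNA_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """Raised for structurally invalid gene models or transcript specs."""


@dataclass(frozen=True)
class ExonModel:
    """One exon: a sequence plus optional alternative acceptor-site offsets.

    ``acceptor_offsets`` maps a site label (``"A"``, ``"B"``, ...) to the 0-based
    offset within the exon where that acceptor variant begins.  Constitutive
    exons leave it empty, which means a single implicit site at offset 0.
    """

    index: int
    sequence: str
    acceptor_offsets: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GeneModelError(f"exon {self.index}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise GeneModelError(
                f"exon {self.index}: alphabet restricted to A/C/G/T, found {sorted(bad)}"
            )
        labels = sorted(self.acceptor_offsets)
        offsets = [self.acceptor_offsets[l] for l in labels]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise GeneModelError(
                f"exon {self.index}: acceptor offsets must increase in label order"
            )
        if any(not (0 <= o < len(self.sequence)) for o in offsets):
            raise GeneModelError(f"exon {self.index}: acceptor offset outside exon")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_multi_acceptor(self) -> bool:
        return len(self.acceptor_offsets) > 1

    def site_offset(self, site: str | None) -> int:
        if site is None:
            if self.is_multi_acceptor:
                raise GeneModelError(
                    f"exon {self.index}: site choice required "
                    f"(one of {sorted(self.acceptor_offsets)})"
                )
            return 0
        try:
            return self.acceptor_offsets[site]
        except KeyError:
            raise GeneModelError(
                f"exon {self.index}: unknown acceptor site {site!r}"
            ) from None

    def site_labels(self) -> list[str]:
        return sorted(self.acceptor_offsets)


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered exon list with optional exons and a start codon."""

    name: str
    exons: Sequence[ExonModel]
    optional_exons: frozenset[int] = frozenset()
    start_codon: tuple[int, int] = (1, 0)  # (exon index, 0-based offset)

    def __post_init__(self) -> None:
        idx = [e.index for e in self.exons]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise GeneModelError("exon indices must be unique and ascending")
        object.__setattr__(self, "optional_exons", frozenset(self.optional_exons))
        unknown = self.optional_exons - set(idx)
        if unknown:
            raise GeneModelError(f"optional_exons not in model: {sorted(unknown)}")
        se, so = self.start_codon
        exon = self.exon(se)
        if not (0 <= so < len(exon)):
            raise GeneModelError("start_codon offset outside its exon")

    def exon(self, index: int) -> ExonModel:
        for e in self.exons:
            if e.index == index:
                return e
        raise GeneModelError(f"gene {self.name!r} has no exon {index}")

    @property
    def exon_indices(self) -> list[int]:
        return [e.index for e in self.exons]

    def multi_acceptor_exons(self) -> list[int]:
        return [e.index for e in self.exons if e.is_multi_acceptor]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "exons": [
                {
                    "index": e.index,
                    "sequence": e.sequence,
                    "acceptor_offsets": dict(e.acceptor_offsets),
                }
                for e in self.exons
            ],
            "optional_exons": sorted(self.optional_exons),
            "start_codon": list(self.start_codon),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneModel":
        return cls(
            name=d["name"],
            exons=[
                ExonModel(e["index"], e["sequence"], dict(e.get("acceptor_offsets", {})))
                for e in d["exons"]
            ],
            optional_exons=frozenset(d.get("optional_exons", [])),
            start_codon=tuple(d["start_codon"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def exons_to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.exons:
                fh.write(f">exon{e.index}\n{e.sequence}\n")


@dataclass(frozen=True)
class TranscriptSpec:
    """One splicing outcome: include/skip per optional exon, site per acceptor exon."""

    include: Mapping[int, bool] = field(default_factory=dict)
    site_choice: Mapping[int, str] = field(default_factory=dict)

    def includes(self, exon_index: int) -> bool:
        return self.include.get(exon_index, True)

    def site(self, exon_index: int) -> str | None:
        return self.site_choice.get(exon_index)

    def label(self) -> str:
        parts = [f"{i}{'+' if v else '-'}" for i, v in sorted(self.include.items())]
        parts += [f"{i}{s}" for i, s in sorted(self.site_choice.items())]
        return "_".join(parts) if parts else "constitutive"


@dataclass(frozen=True)
class JunctionBait:
    """A bait sequence spanning one exon–exon junction.

    ``junction_offset`` is the 0-based bait position of the first acceptor-exon
    base; the donor exon contributes ``[0, junction_offset)``.
    """

    bait_id: str
    sequence: str
    donor: int
    acceptor: int
    site: str | None
    junction_offset: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """First in-frame stop of a spliced transcript, with PTC/frame-shift flags."""

    stop_exon: int
    stop_offset: int  # transcript coordinate of the stop codon's first base
    is_ptc: bool
    frame_shifted: bool


def _validate_spec(model: GeneModel, spec: TranscriptSpec) -> None:
    indices = set(model.exon_indices)
    for i in spec.include:
        if i not in indices:
            raise GeneModelError(f"spec references absent exon {i}")
        if i not in model.optional_exons:
            raise GeneModelError(f"exon {i} is not optional; cannot toggle inclusion")
    for i, s in spec.site_choice.items():
        if i not in indices:
            raise GeneModelError(f"spec references absent exon {i}")
        model.exon(i).site_offset(s)  # validates the label
    for i in model.optional_exons:
        if i not in spec.include:
            raise GeneModelError(f"optional exon {i} has no inclusion flag")
    for i in model.multi_acceptor_exons():
        if i not in spec.site_choice:
            raise GeneModelError(f"multi-acceptor exon {i} has no site choice")


def complete_spec(
    model: GeneModel,
    include: Mapping[int, bool] | None = None,
    site_choice: Mapping[int, str] | None = None,
) -> TranscriptSpec:
    """Fill a partial event assignment into a full valid TranscriptSpec.

    Unspecified optional exons default to included; unspecified multi-acceptor
    exons default to their first (alphabetically lowest) site label.
    """
    inc = {i: True for i in model.optional_exons}
    inc.update(include or {})
    sites = {i: model.exon(i).site_labels()[0] for i in model.multi_acceptor_exons()}
    sites.update(site_choice or {})
    spec = TranscriptSpec(include=dict(sorted(inc.items())),
                          site_choice=dict(sorted(sites.items())))
    _validate_spec(model, spec)
    return spec


def enumerate_transcripts(
    model: GeneModel, events: Iterable[int]
) -> list[TranscriptSpec]:
    """All transcript specs over the Cartesian product of the given events.

    Each event is the index of either an optional exon (in/out) or a
    multi-acceptor exon (site choice).  Exons not listed keep their defaults
    (included; first site).  Order is deterministic: events sorted by exon
    index, inclusion enumerated before exclusion, sites in label order.
    """
    events = sorted(set(events))
    axes: list[list[tuple[str, int, object]]] = []
    for i in events:
        if i in model.optional_exons:
            axes.append([("include", i, True), ("include", i, False)])
        elif i in set(model.exon_indices) and model.exon(i).is_multi_acceptor:
            axes.append([("site", i, s) for s in model.exon(i).site_labels()])
        else:
            raise GeneModelError(
                f"event exon {i} is neither optional nor multi-acceptor in {model.name!r}"
            )
    specs = []
    for combo in itertools.product(*axes):
        include = {i: v for kind, i, v in combo if kind == "include"}
        sites = {i: v for kind, i, v in combo if kind == "site"}
        specs.append(complete_spec(model, include, sites))
    # product of distinct axes cannot repeat, but honor the dedup contract
    seen: set[tuple] = set()
    out = []
    for s in specs:
        key = (tuple(sorted(s.include.items())), tuple(sorted(s.site_choice.items())))
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def transcript_segments(
    model: GeneModel, spec: TranscriptSpec
) -> list[tuple[int, int, int, int]]:
    """Per included exon: (exon_index, site_offset_in_exon, tx_start, tx_end)."""
    _validate_spec(model, spec)
    segs = []
    pos = 0
    for e in model.exons:
        if e.index in model.optional_exons and not spec.includes(e.index):
            continue
        off = e.site_offset(spec.site(e.index)) if e.is_multi_acceptor else 0
        seg_len = len(e) - off
        segs.append((e.index, off, pos, pos + seg_len))
        pos += seg_len
    if not segs:
        raise GeneModelError("spec excludes every exon")
    return segs


def splice_transcript(
    model: GeneModel, spec: TranscriptSpec
) -> tuple[str, list[int]]:
    """Spliced mRNA sequence and 0-based transcript positions of every junction."""
    segs = transcript_segments(model, spec)
    parts = []
    for idx, off, _s, _e in segs:
        parts.append(model.exon(idx).sequence[off:])
    seq = "".join(parts)
    junctions = [e for (_i, _o, _s, e) in segs[:-1]]
    return seq, junctions


def build_junction_bait(
    model: GeneModel,
    donor: int,
    acceptor: int,
    site: str | None = None,
    bait_len: int = 100,
) -> JunctionBait:
    """Bait spanning the donor→acceptor junction, split 50:50 across it.

    The donor contributes its last ``bait_len/2`` nucleotides; the acceptor its
    first ``bait_len/2`` counted from the chosen acceptor-site offset.
    """
    if bait_len % 2:
        raise GeneModelError("bait_len must be even (equal split across the junction)")
    half = bait_len // 2
    d, a = model.exon(donor), model.exon(acceptor)
    if donor >= acceptor:
        raise GeneModelError("donor exon must be upstream of acceptor exon")
    off = a.site_offset(site) if a.is_multi_acceptor or site is not None else 0
    if len(d) < half:
        raise GeneModelError(
            f"donor exon {donor} too short: {len(d)} < {half} nt required"
        )
    remainder = len(a) - off
    if remainder < half:
        raise GeneModelError(
            f"acceptor exon {acceptor} (site {site or 'A'}) too short after offset: "
            f"{remainder} < {half} nt required"
        )
    seq = d.sequence[-half:] + a.sequence[off : off + half]
    bait_id = f"J{donor}-{acceptor}{site or ''}"
    return JunctionBait(bait_id, seq, donor, acceptor, site, half)


def build_constitutive_bait(model: GeneModel, first: int, last: int) -> str:
    """Concatenated sequence of the constitutive exon range ``first..last``."""
    chosen = [e for e in model.exons if first <= e.index <= last]
    if not chosen or chosen[0].index != first or chosen[-1].index != last:
        raise GeneModelError(f"exon range {first}..{last} not fully present")
    bad = [e.index for e in chosen if e.index in model.optional_exons]
    if bad:
        raise GeneModelError(f"range {first}..{last} crosses optional exon(s) {bad}")
    return "".join(e.sequence for e in chosen)


def junction_in_spec(
    model: GeneModel, spec: TranscriptSpec, donor: int, acceptor: int, site: str | None
) -> bool:
    """True iff the spliced transcript of ``spec`` contains this exact junction."""
    segs = transcript_segments(model, spec)
    order = [i for i, *_ in segs]
    if donor not in order or acceptor not in order:
        return False
    if order.index(acceptor) != order.index(donor) + 1:
        return False
    a = model.exon(acceptor)
    if a.is_multi_acceptor and spec.site(acceptor) != site:
        return False
    return True


def annotate_orf(
    model: GeneModel, spec: TranscriptSpec, ejc_rule_nt: int = 50
) -> OrfAnnotation | None:
    """Scan the spliced transcript from the start codon to its first stop.

    ``is_ptc`` follows the exon-junction-complex convention: the stop is a
    premature termination codon when its 3' end lies more than ``ejc_rule_nt``
    nucleotides upstream of the transcript's last exon–exon junction (hence any
    stop within the last exon is never a PTC).  ``frame_shifted`` reports
    whether the total length of skipped exons and trimmed acceptor segments
    upstream of the stop is not a multiple of 3.  Returns ``None`` when no
    in-frame stop exists before the transcript end (a "no stop" outcome).
    """
    segs = transcript_segments(model, spec)
    seq, junctions = splice_transcript(model, spec)
    se, so = model.start_codon
    seg = next((t for t in segs if t[0] == se), None)
    if seg is None:
        raise GeneModelError(f"start-codon exon {se} excluded by spec")
    _idx, off, tx_start, _tx_end = seg
    if so < off:
        raise GeneModelError("start codon removed by acceptor-site trimming")
    start = tx_start + (so - off)
    if len(seq) - start < 3:
        raise GeneModelError("transcript shorter than one codon from start")

    stop_at = None
    for p in range(start, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            stop_at = p
            break
    if stop_at is None:
        return None

    stop_exon = next(i for (i, _o, s, e) in segs if s <= stop_at < e)
    last_junction = junctions[-1] if junctions else 0
    is_ptc = (last_junction - (stop_at + 3)) > ejc_rule_nt

    removed = 0
    for e in model.exons:
        if e.index in model.optional_exons and not spec.includes(e.index):
            if e.index < stop_exon:
                removed += len(e)
        elif e.is_multi_acceptor and e.index <= stop_exon:
            removed += e.site_offset(spec.site(e.index))
    return OrfAnnotation(
        stop_exon=stop_exon,
        stop_offset=stop_at,
        is_ptc=is_ptc,
        frame_shifted=(removed % 3) != 0,
    )


def baits_to_fasta(baits: Iterable, path: str | Path) -> None:
    """Write a bait set as FASTA; junction baits encode their junction offset."""
    with open(path, "w") as fh:
        for b in baits:
            if getattr(b, "junction_offset", None) is not None:
                fh.write(f">{b.bait_id}|off={b.junction_offset}\n{b.sequence}\n")
            else:
                fh.write(f">{b.bait_id}\n{b.sequence}\n")
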