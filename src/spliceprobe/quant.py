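"""Full-identity bait matching, E-value window filtering, junction counting, RPKM.

The quantification strategy mirrors a BLAST-style retrieval pipeline restricted
to ungapped, mismatch-free local alignments: for every read (both strands) the
maximal exact common substring with each bait is located, assigned a
Karlin–Altschul E-value ``E = K·m·n·exp(−λ·reward·L)`` (``m`` bait length,
``n`` database size in nucleotides, ``L`` match length), and kept only when E
falls inside a stringency window (default 4e-60 .. 4e-23) and within a per-bait
retrieval cap (default 20,000, smallest E first).  Surviving matches on a
junction bait count as junction-spanning evidence when they cover the junction
point with at least ``a_min`` matched nucleotides on each side; each read counts
at most once per bait.  Counts are converted to RPKM
(reads per kilobase of bait per million sequenced reads).

Matching is seed-and-run based: all matching k-mers between bait and read are
found by hashed lookup, and a run of ``c`` consecutive k-mer matches along one
diagonal is exactly a maximal common substring of length ``c + k − 1``; a
cascade of halving seed sizes guarantees that matches shorter than the initial
seed are still found exactly, down to a configurable minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import JunctionBait
from .reads import ReadSet, encode_seq, revcomp_codes


@dataclass(frozen=True)
class ScoringParams:
    """Karlin–Altschul parameters for ungapped nucleotide matching.

    Defaults approximate ungapped blastn with +1/−2 scoring (λ in nats per
    score unit); ``reward`` is the score per matched base, so a match of
    length L scores ``reward·L``.
    """

    lambda_: float = 1.28
    K: float = 0.46
    reward: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_, self.K, self.reward) <= 0:
            raise ValueError("scoring parameters must be strictly positive")


@dataclass(frozen=True)
class FilterParams:
    """Retrieval filter: identity, E-value window, hit cap, junction anchors."""

    min_identity: float = 1.0  # fixed: only mismatch-free matches are reported
    evalue_low: float = 4e-60
    evalue_high: float = 4e-23
    max_hits: int = 20_000
    a_min: int = 10  # minimum matched nt on each side of the junction

    def __post_init__(self) -> None:
        if self.min_identity != 1.0:
            raise ValueError("only full identity (min_identity=1.0) is supported")
        if not self.evalue_low < self.evalue_high:
            raise ValueError("require evalue_low < evalue_high")
        if self.max_hits <= 0 or self.a_min < 1:
            raise ValueError("max_hits must be positive and a_min >= 1")


@dataclass(frozen=True)
class Bait:
    """A generic retrieval target; ``junction_offset`` is None for gene-body baits."""

    bait_id: str
    sequence: str
    junction_offset: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """Maximal exact common substring between one read (one strand) and a bait.

    For strand ``"-"`` the coordinates refer to the reverse-complemented read.
    """

    read_id: str
    bait_id: str
    match_len: int
    bait_start: int
    read_start: int
    strand: str
    evalue: float


@dataclass
class FilterResult:
    hits: list[AlignmentHit]
    truncated: bool
    n_before: int


def karlin_altschul_evalue(
    match_len: float, m: int, n: int, params: ScoringParams = ScoringParams()
) -> float:
    """Expected number of chance matches of length >= match_len: K·m·n·e^(−λ·r·L)."""
    if min(match_len, m, n) <= 0:
        raise ValueError("match_len, m and n must be positive")
    return params.K * m * n * math.exp(-params.lambda_ * params.reward * match_len)


def evalue_length_window(
    params: ScoringParams, filt: FilterParams, m: int, n: int
) -> tuple[int, int] | None:
    """Integer match-length window (L_min, L_max) whose E-values fall in the filter.

    Inverts L = (ln(K·m·n) − ln E)/(λ·reward), then verifies the integer bounds
    against the forward formula so floating-point boundary cases are exact.
    Returns None when no integer L in 1..m qualifies.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sizes must be positive")
    s = math.log(params.K) + math.log(m) + math.log(n)
    r = params.lambda_ * params.reward
    lmin = max(1, math.ceil((s - math.log(filt.evalue_high)) / r))
    lmax = math.floor((s - math.log(filt.evalue_low)) / r)

    def ev(L: int) -> float:
        return karlin_altschul_evalue(L, m, n, params)

    while lmin > 1 and ev(lmin - 1) <= filt.evalue_high:
        lmin -= 1
    while lmin <= m and ev(lmin) > filt.evalue_high:
        lmin += 1
    lmax = min(lmax, m)
    while lmax < m and ev(lmax + 1) >= filt.evalue_low:
        lmax += 1
    while lmax >= 1 and ev(lmax) < filt.evalue_low:
        lmax -= 1
    if lmin > lmax or lmin > m:
        return None
    return lmin, lmax


# ---------------------------------------------------------------------------
# seed-and-run exact matching
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Column-oriented hits for a batch of reads against a panel of baits."""

    read: np.ndarray       # read index within the batch
    bait: np.ndarray       # bait index within the panel
    match_len: np.ndarray
    bait_start: np.ndarray
    read_start: np.ndarray
    strand: np.ndarray     # 0 = forward read, 1 = reverse-complemented read

    def __len__(self) -> int:
        return self.read.size

    @classmethod
    def empty(cls) -> "HitTable":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy())

    @classmethod
    def concat(cls, tables: Sequence["HitTable"]) -> "HitTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls.empty()
        return cls(*[
            np.concatenate([getattr(t, f) for t in tables])
            for f in ("read", "bait", "match_len", "bait_start", "read_start", "strand")
        ])


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers per row; windows containing N get -1."""
    n_rows, length = codes.shape
    w = length - k + 1
    if w <= 0:
        return np.empty((n_rows, 0), dtype=np.int64)
    has_n = bool((codes >= 4).any())
    col = (np.minimum(codes, 3) if has_n else codes).astype(np.int64)
    out = col[:, :w].copy()
    for t in range(1, k):
        out *= 4
        out += col[:, t : t + w]
    if has_n:
        bad = np.zeros((n_rows, w), dtype=bool)
        invalid = codes >= 4
        for t in range(k):
            bad |= invalid[:, t : t + w]
        out[bad] = -1
    return out


_PREFILTER_BITS = 22


def _scan_strand(
    read_kmers: np.ndarray,
    table_codes: np.ndarray,
    table_bait: np.ndarray,
    table_pos: np.ndarray,
    k: int,
    strand: int,
    prefilter: np.ndarray | None = None,
) -> HitTable:
    """All maximal common substrings of length >= k, one strand."""
    n_reads, w = read_kmers.shape
    if w == 0 or table_codes.size == 0:
        return HitTable.empty()
    flat = read_kmers.ravel()
    if prefilter is not None:
        # cheap membership pre-test on hashed low bits; false positives are
        # resolved by the exact binary search below
        maybe = prefilter[flat & ((1 << _PREFILTER_BITS) - 1)] & (flat >= 0)
        cand = np.flatnonzero(maybe)
    else:
        cand = np.flatnonzero(flat >= 0)
    if cand.size == 0:
        return HitTable.empty()
    sub = flat[cand]
    lo = np.searchsorted(table_codes, sub, side="left")
    hi = np.searchsorted(table_codes, sub, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return HitTable.empty()
    src = np.repeat(cand, counts)
    starts = np.repeat(lo, counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    trow = starts + offs

    read_i = src // w
    read_pos = (src % w).astype(np.int64)
    bait_i = table_bait[trow].astype(np.int64)
    bait_pos = table_pos[trow].astype(np.int64)
    diag = read_pos - bait_pos

    order = np.lexsort((read_pos, diag, bait_i, read_i))
    read_i, read_pos = read_i[order], read_pos[order]
    bait_i, bait_pos = bait_i[order], bait_pos[order]
    diag = diag[order]

    new_run = np.ones(total, dtype=bool)
    if total > 1:
        new_run[1:] = (
            (read_i[1:] != read_i[:-1])
            | (bait_i[1:] != bait_i[:-1])
            | (diag[1:] != diag[:-1])
            | (read_pos[1:] != read_pos[:-1] + 1)
        )
    run_starts = np.flatnonzero(new_run)
    run_len = np.diff(np.append(run_starts, total))
    return HitTable(
        read=read_i[run_starts],
        bait=bait_i[run_starts],
        match_len=run_len + k - 1,
        bait_start=bait_pos[run_starts],
        read_start=read_pos[run_starts],
        strand=np.full(run_starts.size, strand, dtype=np.int64),
    )


def _best_per_read(table: HitTable) -> HitTable:
    """Keep the single best hit per (bait, read, strand): longest, then smallest
    bait_start, then smallest read_start."""
    if len(table) == 0:
        return table
    order = np.lexsort(
        (table.read_start, table.bait_start, -table.match_len,
         table.strand, table.read, table.bait)
    )
    key = np.stack(
        [table.bait[order], table.read[order], table.strand[order]], axis=1
    )
    first = np.ones(len(table), dtype=bool)
    first[1:] = (key[1:] != key[:-1]).any(axis=1)
    keep = order[first]
    return HitTable(
        table.read[keep], table.bait[keep], table.match_len[keep],
        table.bait_start[keep], table.read_start[keep], table.strand[keep],
    )


def scan_reads(
    bait_seqs: Sequence[str], read_codes: np.ndarray, k: int
) -> HitTable:
    """Best maximal exact match per (bait, read, strand), seed size k.

    Finds every maximal common substring of length >= k; shorter matches are
    invisible at this seed size (see :func:`exact_match_hits` for the exact
    cascade).
    """
    parts_codes, parts_bait, parts_pos = [], [], []
    for bi, seq in enumerate(bait_seqs):
        bc = encode_seq(seq)[None, :]
        if (bc >= 4).any():
            raise ValueError(f"bait {bi} contains ambiguous bases (N)")
        km = _kmer_codes(bc, k)[0]
        parts_codes.append(km)
        parts_bait.append(np.full(km.size, bi, dtype=np.int64))
        parts_pos.append(np.arange(km.size, dtype=np.int64))
    table_codes = np.concatenate(parts_codes) if parts_codes else np.empty(0, np.int64)
    table_bait = np.concatenate(parts_bait) if parts_bait else np.empty(0, np.int64)
    table_pos = np.concatenate(parts_pos) if parts_pos else np.empty(0, np.int64)
    order = np.argsort(table_codes, kind="stable")
    table_codes, table_bait, table_pos = (
        table_codes[order], table_bait[order], table_pos[order]
    )
    prefilter = np.zeros(1 << _PREFILTER_BITS, dtype=bool)
    prefilter[table_codes & ((1 << _PREFILTER_BITS) - 1)] = True

    fwd = _scan_strand(
        _kmer_codes(read_codes, k), table_codes, table_bait, table_pos, k, 0,
        prefilter,
    )
    rev = _scan_strand(
        _kmer_codes(revcomp_codes(read_codes), k), table_codes, table_bait,
        table_pos, k, 1, prefilter,
    )
    return _best_per_read(HitTable.concat([fwd, rev]))


def _coerce_reads(reads) -> ReadSet:
    if isinstance(reads, ReadSet):
        return reads
    seqs = []
    ids = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            ids.append(str(i))
            seqs.append(r)
        elif isinstance(r, tuple):
            ids.append(str(r[0]))
            seqs.append(r[1])
        else:  # SeqRecord-like
            ids.append(str(r.id))
            seqs.append(str(r.seq))
    return ReadSet.from_sequences(seqs, ids=ids)


def exact_match_hits(
    bait,
    reads,
    min_len: int = 1,
    seed_len: int = 16,
    db_size: int | None = None,
    scoring: ScoringParams = ScoringParams(),
) -> list[AlignmentHit]:
    """Maximal exact common substring per (read, strand) against one bait.

    Exactness guarantee: a cascade of halving seed sizes rescans reads that
    produced no hit at the larger seed, down to the first seed <= ``min_len``,
    so every reported length equals the true longest-common-substring length
    whenever that length is >= ``min_len``.  E-values use ``db_size`` (default:
    total nucleotides in the read set).
    """
    bait_seq = bait.sequence if hasattr(bait, "sequence") else str(bait)
    bait_id = getattr(bait, "bait_id", "bait")
    rs = _coerce_reads(reads)
    if len(rs) == 0:
        raise ValueError("reads must be non-empty")
    n = db_size if db_size is not None else rs.total_nt
    min_len = max(1, min_len)

    k0 = min(seed_len, len(bait_seq), rs.read_length)
    levels = [k0]
    while levels[-1] > min_len:
        levels.append(max(1, levels[-1] // 2))

    found: dict[tuple[int, int], tuple] = {}
    pending = {0: np.arange(len(rs)), 1: np.arange(len(rs))}
    for k in levels:
        idx_union = np.unique(np.concatenate([pending[0], pending[1]]))
        if idx_union.size == 0:
            break
        sub = rs.codes[idx_union]
        table = scan_reads([bait_seq], sub, k)
        for j in range(len(table)):
            ri = int(idx_union[table.read[j]])
            st = int(table.strand[j])
            key = (ri, st)
            if key not in found:
                found[key] = (
                    int(table.match_len[j]),
                    int(table.bait_start[j]),
                    int(table.read_start[j]),
                )
        for st in (0, 1):
            pending[st] = np.array(
                [i for i in pending[st] if (int(i), st) not in found], dtype=np.int64
            )

    hits = []
    for (ri, st), (L, bs, qs) in sorted(found.items()):
        if L < min_len:
            continue
        hits.append(
            AlignmentHit(
                read_id=rs.read_id(ri),
                bait_id=bait_id,
                match_len=L,
                bait_start=bs,
                read_start=qs,
                strand="+" if st == 0 else "-",
                evalue=karlin_altschul_evalue(L, len(bait_seq), n, scoring),
            )
        )
    return hits


def filter_hits(
    hits: Sequence[AlignmentHit],
    filt: FilterParams,
    params: ScoringParams,
    n: int,
    m: int | None = None,
) -> FilterResult:
    """Keep hits inside the E-value window, capped at max_hits (smallest E first).

    E-values are recomputed from match lengths against database size ``n`` so
    the result does not depend on how the hits were produced.  Ties at the cap
    are broken by original hit order.
    """
    scored = []
    for h in hits:
        # recompute only when a bait length is supplied; otherwise trust the hit
        e = karlin_altschul_evalue(h.match_len, m, n, params) if m else h.evalue
        if filt.evalue_low <= e <= filt.evalue_high:
            scored.append((e, h))
    truncated = len(scored) > filt.max_hits
    if truncated:
        order = sorted(range(len(scored)), key=lambda i: (scored[i][0], i))
        scored = [scored[i] for i in sorted(order[: filt.max_hits])]
    kept = [
        h if h.evalue == e else AlignmentHit(
            h.read_id, h.bait_id, h.match_len, h.bait_start, h.read_start,
            h.strand, e,
        )
        for e, h in scored
    ]
    return FilterResult(hits=kept, truncated=truncated, n_before=len(hits))


def count_junction_reads(
    hits: Sequence[AlignmentHit], bait: JunctionBait | Bait, filt: FilterParams
) -> int:
    """Reads whose match covers the junction with >= a_min matched nt per side."""
    off = bait.junction_offset
    if off is None:
        raise ValueError(f"bait {bait.bait_id} has no junction offset")
    qualifying = set()
    for h in hits:
        left = off - h.bait_start
        right = h.bait_start + h.match_len - off
        if left >= filt.a_min and right >= filt.a_min:
            qualifying.add(h.read_id)
    return len(qualifying)


def count_bait_reads(hits: Sequence[AlignmentHit]) -> int:
    """Distinct reads with any surviving hit (gene-body baits, no junction rule)."""
    return len({h.read_id for h in hits})


def compute_rpkm(
    counts: Mapping[str, int], bait_lens: Mapping[str, int], total_reads: int
) -> pd.DataFrame:
    """RPKM = count / ((bait_len/1000) · (total_reads/1e6)) per bait."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rows = []
    for bait_id, count in counts.items():
        if count < 0:
            raise ValueError(f"negative count for {bait_id}")
        blen = bait_lens[bait_id]
        rpkm = count / ((blen / 1000.0) * (total_reads / 1e6))
        rows.append(
            {"bait_id": bait_id, "read_count": int(count), "bait_len": int(blen),
             "total_reads": int(total_reads), "rpkm": rpkm}
        )
    return pd.DataFrame(rows)


def usage_fractions(values):
    """Normalize sibling-junction abundances to fractions summing to 1.

    Accepts a mapping (label -> value) or a sequence; returns the same shape.
    Returns None when every value is zero (undefined usage), rather than NaNs.
    """
    if isinstance(values, Mapping):
        keys = list(values)
        vec = np.asarray([values[k] for k in keys], dtype=float)
    else:
        keys = None
        vec = np.asarray(list(values), dtype=float)
    if vec.size == 0 or (vec < 0).any():
        raise ValueError("need >=1 non-negative sibling values")
    total = vec.sum()
    if total == 0:
        return None
    frac = vec / total
    return dict(zip(keys, frac)) if keys is not None else frac


def junction_ratio(rpkm_numerator: float, rpkm_denominator: float):
    """Plain RPKM ratio; None (flagged) when the denominator is zero."""
    if rpkm_denominator == 0:
        return None
    return rpkm_numerator / rpkm_denominator


# ---------------------------------------------------------------------------
# per-sample vectorized quantification
# ---------------------------------------------------------------------------

def quantify_sample(
    baits: Sequence,
    reads: ReadSet,
    scoring: ScoringParams = ScoringParams(),
    filt: FilterParams = FilterParams(),
    seed_len: int = 16,
) -> tuple[dict[str, int], dict]:
    """Junction-spanning (or gene-body) read counts per bait for one sample.

    The E-value window is converted per bait into an exact match-length window
    for this sample's database size, the read set is scanned once per strand
    for all baits jointly, and hits are filtered, capped (smallest E first) and
    deduplicated per read.  Returns ``(counts, metadata)`` where metadata holds
    the database size, per-bait length windows and truncation flags.
    """
    n = reads.total_nt
    windows = {}
    for b in baits:
        windows[b.bait_id] = evalue_length_window(scoring, filt, len(b.sequence), n)

    usable = [b for b in baits if windows[b.bait_id] is not None]
    l_mins = [windows[b.bait_id][0] for b in usable]
    k = max(1, min([seed_len, reads.read_length] + l_mins)) if usable else seed_len

    counts = {b.bait_id: 0 for b in baits}
    truncated = {b.bait_id: False for b in baits}
    if usable:
        table = scan_reads([b.sequence for b in usable], reads.codes, k)
        for bi, b in enumerate(usable):
            lmin, lmax = windows[b.bait_id]
            mask = (table.bait == bi) & (table.match_len >= lmin) & (table.match_len <= lmax)
            idx = np.flatnonzero(mask)
            if idx.size > filt.max_hits:
                order = np.lexsort(
                    (table.strand[idx], table.read[idx], -table.match_len[idx])
                )
                idx = idx[order][: filt.max_hits]
                truncated[b.bait_id] = True
            off = getattr(b, "junction_offset", None)
            if off is None:
                counts[b.bait_id] = int(np.unique(table.read[idx]).size)
            else:
                left = off - table.bait_start[idx]
                right = table.bait_start[idx] + table.match_len[idx] - off
                ok = (left >= filt.a_min) & (right >= filt.a_min)
                counts[b.bait_id] = int(np.unique(table.read[idx][ok]).size)
    meta = {
        "db_size_nt": int(n),
        "total_reads": len(reads),
        "length_windows": windows,
        "truncated": truncated,
        "seed_len": int(k),
    }
    return counts, meta
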