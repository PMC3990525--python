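"""Core mapping algorithm: seeding, hotspot refinement, seed step-down.

A read is mapped in stages of decreasing seed length.  At each stage the read
is cut into non-overlapping tiling seeds (plus one end-anchored seed); each
seed is looked up in the segment's exact-match table; matches vote for a
candidate alignment start (match position minus seed offset), and starts
supported by at least one seed become *hotspots*.  Hotspots are refined in
support order, either by Hamming distance (indel detection off) or by a
banded unit-cost edit alignment with the band half-width equal to the indel
allowance.  Accepted alignments across all segments are merged and the single
best (minimal mismatches + indel bases) location is reported, with a
uniqueness flag when no other location ties.

Reads left unmapped at one stage are retried with the seed length reduced by
a fixed step (default 14 -> 12 -> ... down to the minimum seed length).  By
the pigeonhole principle a read of length >= n*(f+1) with at most f
substitutions always keeps one clean seed, so short seeds act as a rescue
path for the error-rich minority of reads while most reads are resolved
cheaply at the longest seed length.

Segments are independent work units: processing them serially or on any
number of worker processes yields bit-identical output, because candidates
are de-duplicated on global coordinates and merged with a deterministic
tie-break.
"""

from __future__ import annotations

from collections import defaultdict
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .preprocess import Read
from .refindex import (
    ReferenceSegment,
    SeedIndex,
    build_seed_index,
    encode_read,
    revcomp_codes,
    segment_reference,
)

FORWARD = "+"
REVERSE = "-"


@dataclass
class MapParams:
    """Mapping parameters.

    E: maximum total errors (mismatches + indel bases) per read.
    I: maximum indel bases (0 disables indel detection entirely).
    S: minimum seed length — the step-down floor.
    initial_seed / step: starting seed length and per-stage decrement.
    L: optional read-length cap applied before mapping.
    segment_size / overlap: reference segmentation; overlap defaults to the
        maximum read length plus 2*I so every alignment window (padded by the
        indel band) is wholly contained in at least one segment.
    max_hotspots_refined: per read per segment cap on refined hotspots,
        applied in support-descending order.
    """

    E: int = 7
    I: int = 0
    S: int = 12
    initial_seed: int = 14
    step: int = 2
    L: int | None = None
    segment_size: int = 50_000_000
    overlap: int | None = None
    max_hotspots_refined: int = 1024

    def __post_init__(self) -> None:
        if self.E < 0 or self.I < 0:
            raise ValueError("E and I must be >= 0")
        if not 1 <= self.S <= self.initial_seed:
            raise ValueError("need initial_seed >= S >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def stages(self) -> list[int]:
        return list(range(self.initial_seed, self.S - 1, -self.step))


class Hotspot(NamedTuple):
    source_id: str
    strand: str
    cand_start: int  # 0-based global start implied by the seed votes
    support: int


class Candidate(NamedTuple):
    source_id: str
    pos: int
    strand: str
    mismatches: int
    indels: int
    cigar: str


@dataclass
class MappingResult:
    read_id: str
    source_id: str
    pos: int  # 0-based global alignment start
    strand: str
    mismatches: int
    indels: int
    cigar: str
    unique: bool
    stage: int  # seed length at which the read was mapped


@dataclass
class StageTally:
    seed_len: int
    mapped: int
    remaining: int


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def extract_seeds(codes: np.ndarray, seed_len: int) -> list[tuple[int, int]]:
    """(offset, 2-bit value) for tiling seeds at 0, n, 2n, ... plus one
    end-anchored seed; seeds containing non-ACGT bases are dropped."""
    m = len(codes)
    if m < seed_len:
        return []
    offsets = list(range(0, m - seed_len + 1, seed_len))
    if offsets[-1] != m - seed_len:
        offsets.append(m - seed_len)
    out = []
    for off in offsets:
        chunk = codes[off : off + seed_len]
        if np.any(chunk >= 4):
            continue
        v = 0
        for c in chunk:
            v = v * 4 + int(c)
        out.append((off, v))
    return out


def find_hotspots(
    read: Read | np.ndarray,
    index: SeedIndex,
    seed_len: int,
    indel_allowance: int = 0,
) -> list[Hotspot]:
    """Hotspots for the forward read and its reverse complement against one
    segment index, sorted by support descending then start ascending."""
    fwd = read if isinstance(read, np.ndarray) else encode_read(read.bases)
    votes: dict[tuple[str, int], int] = defaultdict(int)
    for strand, codes in ((FORWARD, fwd), (REVERSE, revcomp_codes(fwd))):
        for off, val in extract_seeds(codes, seed_len):
            for p in index.lookup_value(val):
                cand = int(p) - off
                if cand >= 0:
                    votes[(strand, cand)] += 1
    grouped = _group_votes(votes, indel_allowance)
    src = index.segment.source_id
    spots = [Hotspot(src, strand, cand, sup) for (strand, cand), sup in grouped]
    spots.sort(key=lambda h: (-h.support, h.cand_start, h.strand))
    return spots


def _group_votes(
    votes: Mapping[tuple[str, int], int], indel_allowance: int
) -> list[tuple[tuple[str, int], int]]:
    """In indel mode, merge candidate starts differing by <= I on the same
    strand into one hotspot keyed by the minimum start."""
    if indel_allowance == 0:
        return list(votes.items())
    by_strand: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for (strand, cand), sup in votes.items():
        by_strand[strand].append((cand, sup))
    merged: list[tuple[tuple[str, int], int]] = []
    for strand, items in by_strand.items():
        items.sort()
        run_start, run_sup, prev = items[0][0], 0, None
        for cand, sup in items:
            if prev is not None and cand - prev > indel_allowance:
                merged.append(((strand, run_start), run_sup))
                run_start, run_sup = cand, 0
            run_sup += sup
            prev = cand
        merged.append(((strand, run_start), run_sup))
    return merged


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def refine_hamming(
    read_codes: np.ndarray,
    segment: ReferenceSegment,
    cand_start: int,
    max_errors: int,
) -> int | None:
    """Mismatch count of the gap-free alignment at ``cand_start`` (global),
    or None if it exceeds the allowance or the window leaves the segment.
    Reference N positions always count as mismatches."""
    local = cand_start - segment.global_start
    m = len(read_codes)
    if local < 0 or local + m > len(segment.codes):
        return None
    mism = int(np.count_nonzero(segment.codes[local : local + m] != read_codes))
    return mism if mism <= max_errors else None


def refine_banded(
    read_codes: np.ndarray,
    segment: ReferenceSegment,
    cand_start: int,
    max_errors: int,
    max_indels: int,
    source_len: int | None = None,
) -> tuple[int, int, str, int] | None:
    """Banded unit-cost edit alignment around ``cand_start``.

    The read is aligned to the reference window padded by the indel allowance
    on both sides (clipped only at the ends of the source sequence, never at
    an interior segment boundary — an interior candidate whose padded window
    leaves the segment is rejected here and picked up by the neighbouring
    segment).  Dynamic programming tracks the minimal mismatch count for each
    number of indel bases g <= I, so the acceptance test
    mismatches + indels <= E and indels <= I is exact.

    Returns (mismatches, indel_bases, cigar, global_pos) or None.
    """
    if max_indels < 1:
        raise ValueError("refine_banded requires an indel allowance >= 1")
    m = len(read_codes)
    gstart = segment.global_start
    gend = gstart + len(segment.codes)
    src_end = source_len if source_len is not None else gend
    want_lo = cand_start - max_indels
    want_hi = cand_start + m + max_indels
    lo = max(0, want_lo)
    hi = min(src_end, want_hi)
    # the (source-clipped) padded window must be inside this segment
    if lo < gstart or hi > gend or hi - lo < m - max_indels:
        return None
    window = segment.codes[lo - gstart : hi - gstart]
    pad = cand_start - lo  # left pad actually available (0..I)
    res = _banded_edit(read_codes, window, pad, max_errors, max_indels)
    if res is None:
        return None
    mism, gaps, cigar, j0 = res
    return mism, gaps, cigar, lo + j0


_INF = 10**9


def _banded_edit(
    read: np.ndarray, window: np.ndarray, pad: int, E: int, I: int
) -> tuple[int, int, str, int] | None:
    """Semi-global banded DP: read fully aligned inside the window, start and
    end free.  State (i, j, g) = read prefix i, window prefix j, g indel
    bases; value = minimal mismatches.  Band: j - i within pad +/- I."""
    m, w = len(read), len(window)
    width = 2 * I + 1
    jlo0 = pad - I

    def band(i: int) -> range:
        lo = max(0, i + jlo0)
        hi = min(w, i + jlo0 + width - 1)
        return range(lo, hi + 1)

    # D[i] maps (j, g) -> mismatches
    D: list[dict[tuple[int, int], int]] = [dict() for _ in range(m + 1)]
    for j in band(0):
        D[0][(j, 0)] = 0  # free leading reference bases: start anywhere
    for i in range(1, m + 1):
        row = D[i]
        prev = D[i - 1]
        ri = read[i - 1]
        for j in band(i):
            for g in range(I + 1):
                best = _INF
                if j >= 1:
                    v = prev.get((j - 1, g), _INF)
                    if v < _INF:
                        wj = window[j - 1]
                        best = v + (0 if (wj == ri and wj < 4) else 1)
                if g >= 1:
                    v = prev.get((j, g - 1), _INF)  # insertion (read base)
                    if v + 0 < best:
                        best = v
                    if j >= 1:
                        v = row.get((j - 1, g - 1), _INF)  # deletion (ref base)
                        if v < best:
                            best = v
                if best < _INF:
                    row[(j, g)] = best
    # pick minimal total, then fewer indels, then leftmost end
    best_key, best_rank = None, None
    for j in band(m):
        for g in range(I + 1):
            v = D[m].get((j, g), _INF)
            if v >= _INF:
                continue
            total = v + g
            if total > E or v > E:
                continue
            rank = (total, g, j)
            if best_rank is None or rank < best_rank:
                best_rank, best_key = rank, (j, g)
    if best_key is None:
        return None
    j, g = best_key
    mism = D[m][(j, g)]
    # traceback; at ties prefer insertion, then diagonal, then deletion
    ops: list[str] = []
    i = m
    while i > 0:
        cur = D[i][(j, g)]
        if g >= 1 and D[i - 1].get((j, g - 1), _INF) == cur:
            ops.append("I")
            i -= 1
            g -= 1
            continue
        if j >= 1:
            v = D[i - 1].get((j - 1, g), _INF)
            wj = window[j - 1]
            cost = 0 if (wj == read[i - 1] and wj < 4) else 1
            if v + cost == cur:
                ops.append("M")
                i -= 1
                j -= 1
                continue
            if g >= 1 and D[i].get((j - 1, g - 1), _INF) == cur:
                ops.append("D")
                j -= 1
                g -= 1
                continue
        raise AssertionError("banded traceback failed")  # pragma: no cover
    ops.reverse()
    cigar = _compress_cigar(ops)
    n_gap = sum(1 for o in ops if o in "ID")
    return mism, n_gap, cigar, j


def _compress_cigar(ops: Sequence[str]) -> str:
    out = []
    run, cur = 0, None
    for o in ops:
        if o == cur:
            run += 1
        else:
            if cur is not None:
                out.append(f"{run}{cur}")
            cur, run = o, 1
    if cur is not None:
        out.append(f"{run}{cur}")
    return "".join(out)


# ---------------------------------------------------------------------------
# per-read stage mapping and merging
# ---------------------------------------------------------------------------

def _refine_hotspots(
    spots: Iterable[Hotspot],
    fwd: np.ndarray,
    rc: np.ndarray,
    segment: ReferenceSegment,
    params: MapParams,
    source_len: int,
) -> list[Candidate]:
    out: list[Candidate] = []
    for h in spots:
        codes = fwd if h.strand == FORWARD else rc
        if params.I == 0:
            mm = refine_hamming(codes, segment, h.cand_start, params.E)
            if mm is not None:
                out.append(
                    Candidate(h.source_id, h.cand_start, h.strand, mm, 0,
                              f"{len(codes)}M")
                )
        else:
            res = refine_banded(
                codes, segment, h.cand_start, params.E, params.I, source_len
            )
            if res is not None:
                mm, ind, cigar, pos = res
                out.append(Candidate(h.source_id, pos, h.strand, mm, ind, cigar))
    return out


def map_read_stage(
    read: Read,
    indexed_segments: Sequence[tuple[ReferenceSegment, SeedIndex]],
    params: MapParams,
    seed_len: int,
    source_lens: Mapping[str, int] | None = None,
) -> list[Candidate]:
    """Map one read at one seed length: collect hotspots per segment, refine
    the most supported ones, and return the candidates achieving the minimal
    error count (mismatches + indel bases) after global de-duplication."""
    fwd = encode_read(read.bases)
    rc = revcomp_codes(fwd)
    cands: list[Candidate] = []
    for segment, index in indexed_segments:
        spots = find_hotspots(fwd, index, seed_len, params.I)
        spots = spots[: params.max_hotspots_refined]
        slen = (
            source_lens[segment.source_id]
            if source_lens is not None
            else segment.global_start + len(segment.codes)
        )
        cands.extend(_refine_hotspots(spots, fwd, rc, segment, params, slen))
    return _minimal_candidates(cands)


def _minimal_candidates(cands: list[Candidate]) -> list[Candidate]:
    if not cands:
        return []
    seen: dict[tuple[str, int, str], Candidate] = {}
    for c in cands:
        seen.setdefault((c.source_id, c.pos, c.strand), c)
    uniq = list(seen.values())
    best = min(c.mismatches + c.indels for c in uniq)
    return [c for c in uniq if c.mismatches + c.indels == best]


def merge_best(
    candidates: Iterable[Candidate], read_id: str, stage: int
) -> MappingResult | None:
    """Pick the single best location.  Ties on the minimal error count are
    broken lexicographically on (source_id, pos, + before -) and flagged as
    non-unique; no candidates means unmapped (None)."""
    minimal = _minimal_candidates(list(candidates))
    if not minimal:
        return None
    minimal.sort(key=lambda c: (c.source_id, c.pos, 0 if c.strand == FORWARD else 1))
    top = minimal[0]
    return MappingResult(
        read_id=read_id,
        source_id=top.source_id,
        pos=top.pos,
        strand=top.strand,
        mismatches=top.mismatches,
        indels=top.indels,
        cigar=top.cigar,
        unique=len(minimal) == 1,
        stage=stage,
    )


# ---------------------------------------------------------------------------
# batched per-segment stage processing (vectorised seed lookup)
# ---------------------------------------------------------------------------

def _segment_stage_candidates(
    segment: ReferenceSegment,
    seed_len: int,
    reads_sub: list[tuple[int, np.ndarray, np.ndarray]],
    params: MapParams,
    source_len: int,
) -> list[tuple[int, list[Candidate]]]:
    """Candidates of every read of ``reads_sub`` against one segment at one
    seed length.  Seed lookups for all reads are batched into two binary
    searches; the result is identical to the per-read path."""
    index = build_seed_index(segment, seed_len)
    vals: list[int] = []
    meta: list[tuple[int, int, int]] = []  # (read slot, strand 0/1, offset)
    for slot, (ridx, fwd, rc) in enumerate(reads_sub):
        for s, codes in ((0, fwd), (1, rc)):
            for off, v in extract_seeds(codes, seed_len):
                vals.append(v)
                meta.append((slot, s, off))
    out: list[tuple[int, list[Candidate]]] = []
    if vals:
        lo, hi = index.lookup_batch(np.asarray(vals, dtype=np.int64))
        votes: dict[int, dict[tuple[str, int], int]] = defaultdict(
            lambda: defaultdict(int)
        )
        positions = index.positions
        for k in np.nonzero(hi > lo)[0]:
            slot, s, off = meta[k]
            strand = FORWARD if s == 0 else REVERSE
            v = votes[slot]
            for p in positions[lo[k] : hi[k]]:
                cand = int(p) - off
                if cand >= 0:
                    v[(strand, cand)] += 1
        src = segment.source_id
        for slot in sorted(votes):
            ridx, fwd, rc = reads_sub[slot]
            grouped = _group_votes(votes[slot], params.I)
            spots = [Hotspot(src, st, c, sup) for (st, c), sup in grouped]
            spots.sort(key=lambda h: (-h.support, h.cand_start, h.strand))
            spots = spots[: params.max_hotspots_refined]
            cands = _refine_hotspots(spots, fwd, rc, segment, params, source_len)
            if cands:
                out.append((ridx, cands))
    return out


def _worker(args) -> list[tuple[int, list[Candidate]]]:
    return _segment_stage_candidates(*args)


# ---------------------------------------------------------------------------
# iterative step-down controller
# ---------------------------------------------------------------------------

def iterative_map(
    reads: Sequence[Read],
    references: Mapping[str, str],
    params: MapParams,
    workers: int = 1,
    progress=None,
) -> tuple[list[MappingResult | None], list[StageTally]]:
    """Map reads through the seed-length step-down loop.

    Returns per-read results (None = unmapped), aligned with the input order,
    plus per-stage tallies.  Output is invariant to segmentation size, segment
    processing order and worker count.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if params.L is not None:
        reads = [
            Read(r.read_id, r.bases[: params.L],
                 None if r.quals is None else list(r.quals[: params.L]))
            for r in reads
        ]
    results: list[MappingResult | None] = [None] * len(reads)
    tallies: list[StageTally] = []
    if not reads:
        return results, tallies
    lmax = max(len(r.bases) for r in reads)
    overlap = params.overlap if params.overlap is not None else lmax + 2 * params.I
    if params.segment_size <= overlap:
        raise ValueError(
            f"segment_size ({params.segment_size}) must exceed the segment "
            f"overlap ({overlap})"
        )
    segments = segment_reference(references, params.segment_size, overlap)
    source_lens = {name: len(seq) for name, seq in references.items()}
    codes = [(i, encode_read(r.bases)) for i, r in enumerate(reads)]
    active = [(i, c, revcomp_codes(c)) for i, c in codes]
    for seed_len in params.stages():
        if not active:
            break
        per_read: dict[int, list[Candidate]] = defaultdict(list)
        tasks = [
            (seg, seed_len, active, params, source_lens[seg.source_id])
            for seg in segments
        ]
        if workers == 1 or len(segments) == 1:
            chunks = [_worker(t) for t in tasks]
        else:
            with ProcessPoolExecutor(max_workers=workers) as ex:
                chunks = list(ex.map(_worker, tasks))
        for chunk in chunks:
            for ridx, cands in chunk:
                per_read[ridx].extend(cands)
        mapped_now = 0
        still: list[tuple[int, np.ndarray, np.ndarray]] = []
        for item in active:
            ridx = item[0]
            res = merge_best(per_read.get(ridx, []), reads[ridx].read_id, seed_len)
            if res is None:
                still.append(item)
            else:
                results[ridx] = res
                mapped_now += 1
        active = still
        tallies.append(StageTally(seed_len, mapped_now, len(active)))
        if progress is not None:
            progress(tallies[-1])
    return results, tallies


def run_parallel(
    reads: Sequence[Read],
    references: Mapping[str, str],
    params: MapParams,
    workers: int,
) -> tuple[list[MappingResult | None], list[StageTally]]:
    """Multi-worker entry point; output is bit-identical to a serial run."""
    return iterative_map(reads, references, params, workers=workers)
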