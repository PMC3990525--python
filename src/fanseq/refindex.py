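"""Reference segmentation and exact-match seed lookup tables.

A large reference is split into overlapping segments so that each segment can
be processed independently (and in parallel) with bounded memory.  Adjacent
segments overlap by at least the maximum read length, which guarantees that
every alignment window of a read is wholly contained in at least one segment;
de-duplication on global coordinates then makes the segmentation invisible in
the final output.

Each segment carries a seed index: a lookup table from every fixed-length
subsequence (k-mer) over {A,C,G,T} to the sorted global positions where it
occurs on the forward strand.  k-mers touching an ambiguous base (``N``) are
never indexed, so hard-masked regions are skipped automatically; soft-masked
(lower-case) bases are upper-cased before indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

# Base encoding: A=0 C=1 G=2 T=3; anything else (N, IUPAC ambiguity) = 4 in
# references and 5 in reads, so a read N never silently "matches" a masked
# reference position.
_REF_LUT = np.full(256, 4, dtype=np.uint8)
_READ_LUT = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _REF_LUT[ord(_b)] = _i
    _REF_LUT[ord(_b.lower())] = _i
    _READ_LUT[ord(_b)] = _i
    _READ_LUT[ord(_b.lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGTNN", dtype=np.uint8)
# complement table over the 6 codes (N stays non-ACGT)
_COMP = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)


def encode_reference(seq: str) -> np.ndarray:
    """Encode a reference sequence to uint8 codes (A=0..T=3, other=4)."""
    return _REF_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_read(seq: str) -> np.ndarray:
    """Encode a read to uint8 codes (A=0..T=3, other=5)."""
    return _READ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


@dataclass
class ReferenceSegment:
    """A slice of one reference sequence with global-coordinate bookkeeping.

    ``overlap`` is the number of bases shared with the *next* segment of the
    same source (0 for the last segment).
    """

    segment_id: str
    source_id: str
    global_start: int
    codes: np.ndarray  # uint8 reference codes
    overlap: int

    @property
    def bases(self) -> str:
        return decode(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


def segment_reference(
    references: Mapping[str, str] | Iterable[tuple[str, str]],
    segment_size: int,
    overlap: int,
) -> list[ReferenceSegment]:
    """Tile each reference with segments of ``segment_size`` stepping by
    ``segment_size - overlap``; the last segment may be shorter.

    Every substring of length <= overlap of a source is wholly contained in at
    least one segment, and removing the overlaps reconstructs the source.
    """
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if segment_size <= overlap:
        raise ValueError(
            f"segment_size ({segment_size}) must exceed overlap ({overlap})"
        )
    items = references.items() if isinstance(references, Mapping) else references
    step = segment_size - overlap
    segments: list[ReferenceSegment] = []
    for name, seq in items:
        if len(seq) == 0:
            raise ValueError(f"reference {name!r} is empty")
        codes = encode_reference(seq)
        n = len(codes)
        starts = list(range(0, max(1, n - overlap), step))
        for k, start in enumerate(starts):
            chunk = codes[start : start + segment_size]
            is_last = k == len(starts) - 1
            segments.append(
                ReferenceSegment(
                    segment_id=f"{name}:{start}",
                    source_id=name,
                    global_start=start,
                    codes=chunk,
                    overlap=0 if is_last else segment_size - step,
                )
            )
    return segments


def _window_kmers(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every length-n window; returns (values, valid_mask)."""
    m = len(codes) - n + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(m, dtype=np.int64)
    bad = (codes >= 4).astype(np.int32)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (bad_cum[n:] - bad_cum[:-n]) == 0
    safe = np.where(codes >= 4, 0, codes).astype(np.int64)
    for j in range(n):
        vals = vals * 4 + safe[j : j + m]
    return vals, valid


def kmer_value(codes: np.ndarray) -> int:
    """2-bit pack a single k-mer; -1 if it contains a non-ACGT base."""
    if np.any(codes >= 4):
        return -1
    v = 0
    for c in codes:
        v = v * 4 + int(c)
    return int(v)


@dataclass
class SeedIndex:
    """Exact-match lookup table for one segment at a fixed seed length.

    Internally the (kmer value, global position) pairs are stored sorted by
    value then position, so a query is two binary searches.  The dict-style
    ``table`` view exists for inspection on small segments; lookups through
    either surface agree.
    """

    segment: ReferenceSegment
    seed_len: int
    _kmers: np.ndarray = field(repr=False)
    _positions: np.ndarray = field(repr=False)

    @property
    def n_indexed(self) -> int:
        return len(self._positions)

    def lookup_value(self, value: int) -> np.ndarray:
        """Sorted global positions of a 2-bit packed k-mer (empty if none)."""
        lo = np.searchsorted(self._kmers, value, side="left")
        hi = np.searchsorted(self._kmers, value, side="right")
        return self._positions[lo:hi]

    def lookup(self, kmer: str) -> np.ndarray:
        if len(kmer) != self.seed_len:
            raise ValueError("query length != seed_len")
        v = kmer_value(encode_read(kmer))
        if v < 0:
            return np.empty(0, dtype=np.int64)
        return self.lookup_value(v)

    def lookup_batch(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised query: (lo, hi) slice bounds into the position array."""
        lo = np.searchsorted(self._kmers, values, side="left")
        hi = np.searchsorted(self._kmers, values, side="right")
        return lo, hi

    @property
    def positions(self) -> np.ndarray:
        return self._positions

    def to_dict(self) -> dict[str, list[int]]:
        """Materialise the full table (small segments only)."""
        out: dict[str, list[int]] = {}
        seg = self.segment
        for v, p in zip(self._kmers, self._positions):
            local = int(p) - seg.global_start
            key = decode(seg.codes[local : local + self.seed_len])
            out.setdefault(key, []).append(int(p))
        return out


def build_seed_index(segment: ReferenceSegment, seed_len: int) -> SeedIndex:
    """Index every N-free ``seed_len``-mer of the segment by global position."""
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    vals, valid = _window_kmers(segment.codes, seed_len)
    local = np.nonzero(valid)[0]
    vals = vals[local]
    order = np.argsort(vals, kind="stable")  # stable keeps positions sorted
    return SeedIndex(
        segment=segment,
        seed_len=seed_len,
        _kmers=vals[order],
        _positions=(local[order] + segment.global_start).astype(np.int64),
    )
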