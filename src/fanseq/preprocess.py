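"""Read quality control applied before mapping.

Three rules, applied in order:

1. quality truncation — a read is cut just before the first base whose Phred
   score falls below a threshold (default Q20, i.e. 1% call-error);
2. length filter — reads shorter than a minimum (default 18 nt) are discarded;
3. low-complexity filter — reads dominated by a homopolymer or a dinucleotide
   tandem repeat covering more than half of the read are discarded, since such
   reads cannot be placed unambiguously.

The rules only trim or drop reads; bases are never edited.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Sequence


@dataclass
class Read:
    """A single-end read: identifier, bases, optional per-base Phred scores."""

    read_id: str
    bases: str
    quals: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


def truncate_at_quality(read: Read, threshold: int = 20) -> Read:
    """Return the prefix ending just before the first base with quality below
    ``threshold``.  Reads without qualities pass through unchanged."""
    if read.quals is None:
        return read
    cut = len(read.bases)
    for i, q in enumerate(read.quals):
        if q < threshold:
            cut = i
            break
    if cut == len(read.bases):
        return read
    return Read(read.read_id, read.bases[:cut], list(read.quals[:cut]))


def length_filter(reads: Iterable[Read], min_len: int = 18) -> Iterator[Read]:
    """Keep reads of at least ``min_len`` bases, preserving order."""
    for r in reads:
        if len(r.bases) >= min_len:
            yield r


def _longest_run(s: str, period: int) -> int:
    """Length (nt) of the longest stretch repeating with the given period."""
    n = len(s)
    if n == 0:
        return 0
    if n <= period:
        return n
    best = run = period
    for i in range(period, n):
        if s[i] == s[i - period]:
            run += 1
        else:
            run = period
        if run > best:
            best = run
    return best


def longest_homopolymer(bases: str) -> int:
    return _longest_run(bases, 1)


def longest_dinucleotide_repeat(bases: str) -> int:
    """Longest tandem repetition of any 2-nt unit, measured in nucleotides.

    A period-2 stretch whose unit is AA, CC, GG or TT is a homopolymer and is
    caught by the homopolymer rule anyway; it is not excluded here because the
    filter condition is a disjunction of the two rules.
    """
    return _longest_run(bases, 2)


def low_complexity_filter(read: Read) -> bool:
    """True = keep.  Discard iff the longest homopolymer or dinucleotide
    tandem repeat is strictly longer than half the read length."""
    if len(read.bases) == 0:
        raise ValueError("low_complexity_filter requires a non-empty read")
    half = Fraction(len(read.bases), 2)
    if longest_homopolymer(read.bases) > half:
        return False
    if longest_dinucleotide_repeat(read.bases) > half:
        return False
    return True


def preprocess_reads(
    reads: Iterable[Read],
    quality_threshold: int = 20,
    min_len: int = 18,
    complexity: bool = True,
) -> list[Read]:
    """Full QC pipeline: truncate -> length filter -> complexity filter."""
    truncated = (truncate_at_quality(r, quality_threshold) for r in reads)
    kept = length_filter(truncated, min_len)
    if not complexity:
        return list(kept)
    return [r for r in kept if low_complexity_filter(r)]
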