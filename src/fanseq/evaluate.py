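"""Scoring mapping results against simulation truth.

Every simulated read has one of three outcomes: mapped to its correct
position (C), mapped to a wrong position (I), or unmapped (U).  From these
tallies, sensitivity = (C + I) / (C + I + U) — the fraction of reads mapped
anywhere — and correctness = C / (C + I) — the fraction of mapped reads
placed at their true origin.  An optional position tolerance absorbs the
legitimate start shifts introduced by indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .mapper import MappingResult
from .simulate import TruthRecord


@dataclass
class EvalCounts:
    C: int = 0  # mapped to the correct position
    I: int = 0  # mapped to a wrong position
    U: int = 0  # unmapped

    @property
    def total(self) -> int:
        return self.C + self.I + self.U


def classify(
    results: Iterable[MappingResult],
    truth: Mapping[str, TruthRecord] | Iterable[TruthRecord],
    tolerance: int = 0,
) -> EvalCounts:
    """Tally C/I/U.  A result is correct iff source and strand match the
    truth and the reported start is within ``tolerance`` nt of the true
    start.  Truth reads absent from the results count as unmapped."""
    if not isinstance(truth, Mapping):
        truth = {t.read_id: t for t in truth}
    counts = EvalCounts()
    seen = set()
    for res in results:
        if res is None:
            continue
        t = truth.get(res.read_id)
        if t is None:
            raise KeyError(f"result for unknown read {res.read_id!r}")
        if res.read_id in seen:
            raise ValueError(f"duplicate result for read {res.read_id!r}")
        seen.add(res.read_id)
        if (
            res.source_id == t.true_source
            and res.strand == t.true_strand
            and abs(res.pos - t.true_pos) <= tolerance
        ):
            counts.C += 1
        else:
            counts.I += 1
    counts.U = len(truth) - len(seen)
    return counts


def sensitivity(counts: EvalCounts) -> float:
    """(C + I) / (C + I + U): fraction of reads mapped anywhere."""
    if counts.total == 0:
        raise ValueError("no reads evaluated")
    return (counts.C + counts.I) / counts.total


def correctness(counts: EvalCounts) -> float:
    """C / (C + I): fraction of mapped reads at their true origin."""
    mapped = counts.C + counts.I
    if mapped == 0:
        raise ValueError("correctness undefined: no reads mapped")
    return counts.C / mapped


def unique_only(results: Iterable[MappingResult]) -> list[MappingResult]:
    """Keep only uniquely mapped reads (no tied best location)."""
    return [r for r in results if r is not None and r.unique]
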