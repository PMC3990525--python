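"""Simulation of error-injected reads with known ground truth.

Emulates benchmark datasets of uniformly drawn single-end reads (default
75 nt) carrying independent per-base substitutions at a chosen rate (2% and
4% are the standard conditions here), optionally with 1-nt indels.  Every
read is recorded with the exact edit script applied, so mapping results can
be scored as correct / incorrect / unmapped.  Reads failing the
low-complexity rule (homopolymer or dinucleotide repeat spanning more than
half the read) are removed from both the read set and the truth table, as
such reads are inherently ambiguous to place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Read, low_complexity_filter

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_STR = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


@dataclass
class TruthRecord:
    read_id: str
    true_source: str
    true_pos: int  # 0-based start of the source window
    true_strand: str
    injected_mismatches: int
    injected_indels: int


def random_genome(length: int, seed: int, name: str = "sim_ref") -> tuple[str, str]:
    """An i.i.d. uniform ACGT sequence; reproducible for a given seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return name, seq


def simulate_reads(
    reference: tuple[str, str],
    n_reads: int,
    read_len: int = 75,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    strand_mix: float = 0.5,
    seed: int = 0,
    complexity_filter: bool = True,
    qual: int = 40,
) -> tuple[list[Read], list[TruthRecord]]:
    """Draw reads uniformly from the reference and inject errors.

    Substitutions flip each base independently with probability ``sub_rate``
    to one of the three other bases; with ``indel_rate`` > 0 each position
    additionally triggers a 1-nt insertion or deletion (equal odds).
    ``strand_mix`` is the probability of drawing the reverse strand.  The
    truth record stores the window start on the forward reference and the
    error counts actually applied.
    """
    name, seq = reference
    if len(seq) < read_len:
        raise ValueError("reference shorter than read length")
    for r, label in ((sub_rate, "sub_rate"), (indel_rate, "indel_rate")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{label} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref_codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code_of[ord(b)] = i
    reads: list[Read] = []
    truth: list[TruthRecord] = []
    quals_cache: dict[int, list[int]] = {}
    for i in range(n_reads):
        start = int(rng.integers(0, len(seq) - read_len + 1))
        strand = "-" if rng.random() < strand_mix else "+"
        window = seq[start : start + read_len]
        bases = revcomp(window) if strand == "-" else window
        codes = code_of[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
        sub_mask = rng.random(read_len) < sub_rate
        n_sub = int(sub_mask.sum())
        if n_sub:
            shift = rng.integers(1, 4, size=n_sub)
            codes = codes.copy()
            codes[sub_mask] = (codes[sub_mask] + shift) % 4
        out = _BASES[codes].tobytes().decode("ascii")
        n_ind = 0
        if indel_rate > 0.0:
            out, n_ind = _inject_indels(out, indel_rate, rng)
        if complexity_filter and not low_complexity_filter(Read("t", out)):
            continue
        rid = f"sim{i:06d}"
        q = quals_cache.setdefault(len(out), [qual] * len(out))
        reads.append(Read(rid, out, list(q)))
        truth.append(TruthRecord(rid, name, start, strand, n_sub, n_ind))
    del ref_codes
    return reads, truth


def _inject_indels(
    bases: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    out = []
    n_ind = 0
    for ch in bases:
        if rng.random() < rate:
            n_ind += 1
            if rng.random() < 0.5:
                # insertion of a random base before this one
                out.append("ACGT"[int(rng.integers(0, 4))])
                out.append(ch)
            else:
                continue  # deletion of this base
        else:
            out.append(ch)
    return "".join(out), n_ind
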