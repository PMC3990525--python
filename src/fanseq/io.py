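"""File formats: FASTA/FASTQ input, TSV and SAM output, truth tables.

The native result format is a TSV with one row per mapped read
(read_id, source, pos0, strand, mismatches, indels, cigar, unique, stage);
SAM output carries the same alignment (1-based POS, CIGAR, NM tag) with
MAPQ 30 for unique and 0 for non-unique placements.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .mapper import MappingResult
from .preprocess import Read
from .simulate import TruthRecord, revcomp

SAM_MAPQ_UNIQUE = 30

RESULT_COLUMNS = (
    "read_id source pos0 strand mismatches indels cigar unique stage".split()
)


def read_fasta(path: str) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines, mixed case allowed) -> {name: seq}."""
    refs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        refs[rec.id] = str(rec.seq)
    if not refs:
        raise ValueError(f"no FASTA records in {path}")
    return refs


def read_reads(path: str, phred64: bool = False) -> list[Read]:
    """Reads from FASTQ (with qualities) or FASTA (without)."""
    fmt = _sniff_format(path)
    if fmt == "fasta":
        return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    fq = "fastq-illumina" if phred64 else "fastq"
    return [
        Read(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(path, fq)
    ]


def _sniff_format(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    raise ValueError(f"{path} is empty")


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with _atomic(path) as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else [40] * len(r.bases)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qstr}\n")


def write_fasta(references: Mapping[str, str], path: str, width: int = 70) -> None:
    with _atomic(path) as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_results_tsv(results: Iterable[MappingResult | None], path: str) -> None:
    with _atomic(path) as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            if r is None:
                continue
            fh.write(
                f"{r.read_id}\t{r.source_id}\t{r.pos}\t{r.strand}\t"
                f"{r.mismatches}\t{r.indels}\t{r.cigar}\t"
                f"{int(r.unique)}\t{r.stage}\n"
            )


def read_results_tsv(path: str) -> list[MappingResult]:
    out: list[MappingResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != RESULT_COLUMNS:
            raise ValueError(f"{path}: unexpected result header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                MappingResult(
                    read_id=f[0], source_id=f[1], pos=int(f[2]), strand=f[3],
                    mismatches=int(f[4]), indels=int(f[5]), cigar=f[6],
                    unique=bool(int(f[7])), stage=int(f[8]),
                )
            )
    return out


def write_truth_tsv(truth: Iterable[TruthRecord], path: str) -> None:
    with _atomic(path) as fh:
        fh.write("read_id\tsource\tpos0\tstrand\tmismatches\tindels\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.true_source}\t{t.true_pos}\t{t.true_strand}\t"
                f"{t.injected_mismatches}\t{t.injected_indels}\n"
            )


def read_truth_tsv(path: str) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out[f[0]] = TruthRecord(f[0], f[1], int(f[2]), f[3], int(f[4]), int(f[5]))
    return out


def write_sam(
    results: Sequence[MappingResult | None],
    reads: Sequence[Read],
    reference_lengths: Mapping[str, int],
    path: str,
    include_unmapped: bool = True,
) -> None:
    """SAM 1.6 output.  POS is 1-based; reverse-strand records carry the
    reverse-complemented read sequence, as the format requires."""
    if len(results) != len(reads):
        raise ValueError("results must be aligned with reads")
    with _atomic(path) as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, ln in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        fh.write("@PG\tID:fanseq\tPN:fanseq\n")
        for res, read in zip(results, reads):
            if res is None:
                if include_unmapped:
                    seq = read.bases or "*"
                    fh.write(
                        f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t"
                        f"{_qual_str(read)}\n"
                    )
                continue
            flag = 16 if res.strand == "-" else 0
            seq = revcomp(read.bases) if res.strand == "-" else read.bases
            qual = _qual_str(read, reverse=res.strand == "-")
            mapq = SAM_MAPQ_UNIQUE if res.unique else 0
            nm = res.mismatches + res.indels
            fh.write(
                f"{res.read_id}\t{flag}\t{res.source_id}\t{res.pos + 1}\t{mapq}\t"
                f"{res.cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{nm}\n"
            )


def _qual_str(read: Read, reverse: bool = False) -> str:
    if read.quals is None:
        return "*"
    quals = list(read.quals)
    if reverse:
        quals.reverse()
    return "".join(chr(q + 33) for q in quals)


def read_gene_map(path: str) -> dict[str, str]:
    """Two-column TSV: transcript_id <tab> gene_id."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tx, gene = line.split("\t")[:2]
            out[tx] = gene
    return out


class _atomic:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path: str):
        self.path = path

    def __enter__(self):
        d = os.path.dirname(os.path.abspath(self.path))
        fd, self.tmp = tempfile.mkstemp(dir=d, suffix=".part")
        self.fh = os.fdopen(fd, "w")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False
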