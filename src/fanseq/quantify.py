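"""Gene quantification from transcriptome mapping results (rpkM).

Reads mapped to transcript reference sequences are summed per gene after
merging splice variants (an optional transcript-to-gene table; transcripts
without an entry are their own gene).  Abundance is expressed as rpkM —
reads per kilobase of transcript per million mapped reads:

    rpkM = count / ((length_nt / 1000) * (total_mapped / 1e6))

Genes supported by fewer than 10 reads are dropped by default as unreliably
quantified.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .mapper import MappingResult

LENGTH_MODES = ("longest", "mean")


def count_reads(
    results: Iterable[MappingResult],
    transcript_lengths: Mapping[str, int],
    variant_map: Mapping[str, str] | None = None,
    unique_only: bool = False,
) -> dict[str, int]:
    """Per-gene read counts, summed over all splice variants of each gene.

    Unmapped entries (None) are ignored; a mapped source_id missing from the
    transcript table is an error.  ``unique_only`` drops multi-mapped reads.
    """
    variant_map = variant_map or {}
    counts: dict[str, int] = {}
    unknown: set[str] = set()
    for res in results:
        if res is None:
            continue
        if res.source_id not in transcript_lengths:
            unknown.add(res.source_id)
            continue
        if unique_only and not res.unique:
            continue
        gene = variant_map.get(res.source_id, res.source_id)
        counts[gene] = counts.get(gene, 0) + 1
    if unknown:
        raise KeyError(
            "mapped reference ids missing from the transcript table: "
            + ", ".join(sorted(unknown))
        )
    return counts


def rpkm(read_count: int, length_nt: int, total_mapped: int) -> float:
    if length_nt <= 0:
        raise ValueError("transcript length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total mapped read count must be > 0")
    return read_count / ((length_nt / 1000.0) * (total_mapped / 1e6))


def gene_lengths(
    transcript_lengths: Mapping[str, int],
    variant_map: Mapping[str, str] | None = None,
    mode: str = "longest",
) -> dict[str, int]:
    """Effective gene length after variant merging: the longest variant
    (default) or the mean of variant lengths."""
    if mode not in LENGTH_MODES:
        raise ValueError(f"length mode must be one of {LENGTH_MODES}")
    variant_map = variant_map or {}
    per_gene: dict[str, list[int]] = {}
    for tx, ln in transcript_lengths.items():
        per_gene.setdefault(variant_map.get(tx, tx), []).append(ln)
    if mode == "longest":
        return {g: max(ls) for g, ls in per_gene.items()}
    return {g: int(round(sum(ls) / len(ls))) for g, ls in per_gene.items()}


def filter_unreliable(table: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Drop genes with fewer than ``min_reads`` mapped reads."""
    return table[table["read_count"] >= min_reads].reset_index(drop=True)


def quantify_genes(
    results: Iterable[MappingResult],
    transcript_lengths: Mapping[str, int],
    variant_map: Mapping[str, str] | None = None,
    length_mode: str = "longest",
    min_reads: int = 10,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Full pipeline: count per gene, normalise to rpkM, drop unreliable
    genes.  Columns: gene_id, read_count, length_nt, rpkM."""
    counts = count_reads(results, transcript_lengths, variant_map, unique_only)
    total = sum(counts.values())
    lengths = gene_lengths(transcript_lengths, variant_map, length_mode)
    rows = [
        {
            "gene_id": g,
            "read_count": c,
            "length_nt": lengths[g],
            "rpkM": rpkm(c, lengths[g], total),
        }
        for g, c in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "read_count", "length_nt", "rpkM"])
    return filter_unreliable(table, min_reads)
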