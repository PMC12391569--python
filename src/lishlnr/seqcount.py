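"""Ligation-product read counting and FPNM normalization (LISH-seq).

A probe set ligates into a junction sequence: the 3P (acceptor) probe's
target-recognition sequence followed by the 5P (donor) probe's.  Cross
ligation between the 3P probe of one gene and the 5P probe of another
produces a "mismatch" product; the reference set therefore contains one
perfect junction per probe set plus every ordered cross pairing.  Reads
are counted by exact junction match at a configured offset.

Normalization follows the per-million convention: the sum of all mapped
reads (perfect plus mismatch) divided by 1e6 is the scaling factor, each
count divided by it gives FM ("fragments per million"), and FM divided by
the number of probes targeting the gene gives FPNM.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "LigationRef",
    "SeqCountTable",
    "JunctionCollisionError",
    "build_ligation_refs",
    "count_reads",
    "compute_fpnm",
    "matched_ratio",
    "write_refs_fasta",
]

_VALID = set("ACGT")


class JunctionCollisionError(ValueError):
    """Two distinct probe pairings produce an identical junction sequence."""

    def __init__(self, collisions):
        self.collisions = collisions
        super().__init__(
            "identical junction sequences for: "
            + "; ".join(" == ".join(names) for names in collisions)
        )


@dataclass(frozen=True)
class LigationRef:
    """One ligation product: 3P half then 5P half."""

    gene_3p: str
    gene_5p: str
    junction_seq: str
    klass: str  # "perfect" | "mismatch"

    def __post_init__(self):
        if not self.junction_seq or set(self.junction_seq) - _VALID:
            raise ValueError("junction_seq must be non-empty uppercase ACGT")
        expected = "perfect" if self.gene_3p == self.gene_5p else "mismatch"
        if self.klass != expected:
            raise ValueError(
                f"klass {self.klass!r} inconsistent with gene pair "
                f"({self.gene_3p}, {self.gene_5p})"
            )

    @property
    def name(self) -> str:
        return f"{self.gene_3p}__{self.gene_5p}"


@dataclass
class SeqCountTable:
    """Per-reference counts plus per-gene FM/FPNM normalization."""

    refs: list[LigationRef]
    ref_counts: pd.DataFrame      # name, gene_3p, gene_5p, klass, count [, fm]
    total_reads: int              # mapped reads (perfect + mismatch)
    unmapped: int
    gene_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # gene_table columns after compute_fpnm: gene, count, n_probes, fm, fpnm


def build_ligation_refs(
    probe_sets: Sequence[tuple[str, str, str]],
) -> list[LigationRef]:
    """Perfect + ordered-cross-pair mismatch references for the probe sets.

    ``probe_sets`` rows are (gene, seq_3p, seq_5p).  N sets yield N
    perfect and N*(N-1) mismatch references.  Identical junctions from
    distinct pairings raise :class:`JunctionCollisionError` rather than
    being merged silently.
    """
    refs = []
    for g3, s3, _ in probe_sets:
        for g5, _, s5 in probe_sets:
            seq = (s3 + s5).upper()
            klass = "perfect" if g3 == g5 else "mismatch"
            refs.append(LigationRef(gene_3p=g3, gene_5p=g5, junction_seq=seq,
                                    klass=klass))
    seen: dict[str, list[str]] = {}
    for r in refs:
        seen.setdefault(r.junction_seq, []).append(r.name)
    collisions = [names for names in seen.values() if len(names) > 1]
    if collisions:
        raise JunctionCollisionError(collisions)
    return refs


def count_reads(
    fastq_path,
    refs: Sequence[LigationRef],
    read_offset: int = 0,
) -> SeqCountTable:
    """Tally exact junction matches in a FASTQ (optionally gzipped).

    A read counts for a reference iff the junction sequence occurs
    verbatim at ``read_offset``; one substitution anywhere in the window
    makes the read unmapped.  When junctions of different lengths both
    match (one a prefix of another), the longest wins.
    """
    by_seq = {r.junction_seq: i for i, r in enumerate(refs)}
    lengths = sorted({len(s) for s in by_seq}, reverse=True)
    counts = np.zeros(len(refs), dtype=np.int64)
    unmapped = 0

    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            seq = str(rec.seq).upper()
            for L in lengths:
                idx = by_seq.get(seq[read_offset:read_offset + L])
                if idx is not None:
                    counts[idx] += 1
                    break
            else:
                unmapped += 1

    ref_counts = pd.DataFrame({
        "name": [r.name for r in refs],
        "gene_3p": [r.gene_3p for r in refs],
        "gene_5p": [r.gene_5p for r in refs],
        "klass": [r.klass for r in refs],
        "count": counts,
    })
    return SeqCountTable(refs=list(refs), ref_counts=ref_counts,
                         total_reads=int(counts.sum()), unmapped=unmapped)


def compute_fpnm(
    table: SeqCountTable,
    n_probes_per_gene: Mapping[str, int],
) -> SeqCountTable:
    """Fill FM and FPNM columns in place and return the table.

    scaling = total_reads / 1e6; FM = count / scaling (so FM sums to 1e6
    over all references); FPNM(gene) = FM(gene's perfect references) /
    n_probes(gene).
    """
    if table.total_reads <= 0:
        raise ValueError("FPNM undefined: no mapped reads")
    scaling = table.total_reads / 1e6
    table.ref_counts["fm"] = table.ref_counts["count"] / scaling

    perfect = table.ref_counts[table.ref_counts["klass"] == "perfect"]
    genes = perfect["gene_3p"].tolist()
    missing = [g for g in genes if g not in n_probes_per_gene]
    if missing:
        raise ValueError(f"n_probes missing for genes: {missing}")
    gene_table = (
        perfect.groupby("gene_3p", sort=False)
        .agg(count=("count", "sum"), fm=("fm", "sum"))
        .reset_index()
        .rename(columns={"gene_3p": "gene"})
    )
    gene_table["n_probes"] = [int(n_probes_per_gene[g]) for g in gene_table["gene"]]
    gene_table["fpnm"] = gene_table["fm"] / gene_table["n_probes"]
    table.gene_table = gene_table
    return table


def matched_ratio(table: SeqCountTable) -> tuple[int, int, float]:
    """(perfect reads, mismatch reads, ratio); ratio is NaN when no
    mismatch reads were seen."""
    perfect = int(table.ref_counts.loc[table.ref_counts["klass"] == "perfect",
                                       "count"].sum())
    mismatch = int(table.ref_counts.loc[table.ref_counts["klass"] == "mismatch",
                                        "count"].sum())
    ratio = perfect / mismatch if mismatch else float("nan")
    return perfect, mismatch, ratio


def write_refs_fasta(path, refs: Sequence[LigationRef]) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.name} {r.klass}\n{r.junction_seq}\n")
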