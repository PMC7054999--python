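"""Transcript reference set: sequences, ORF annotation, category lists."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

SPECIES = ("human", "yeast")
CLASSES = ("mRNA", "rRNA", "tRNA")


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    species: str
    tclass: str
    gene_symbol: str
    cds_start: int | None = None  # 0-based half-open CDS interval
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"{self.id}: unknown species {self.species!r}")
        if self.tclass not in CLASSES:
            raise ValueError(f"{self.id}: unknown class {self.tclass!r}")
        if self.tclass == "mRNA":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.id}: mRNA requires a CDS interval")
            if not 0 <= self.cds_start < self.cds_end <= len(self.sequence):
                raise ValueError(f"{self.id}: CDS outside the transcript")


@dataclass
class ReferenceSet:
    """All reference transcripts plus gene-category annotations."""

    transcripts: dict[str, Transcript]
    top_genes: frozenset = frozenset()
    ires_genes: frozenset = frozenset()
    mito_rp_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.top_genes = frozenset(self.top_genes)
        self.ires_genes = frozenset(self.ires_genes)
        self.mito_rp_genes = frozenset(self.mito_rp_genes)

    def by_class(self, tclass: str) -> dict[str, str]:
        """id -> sequence for one transcript class (mRNA spans both species)."""
        return {t.id: t.sequence for t in self.transcripts.values()
                if t.tclass == tclass}

    def species_of_gene(self) -> dict[str, str]:
        return {t.gene_symbol: t.species for t in self.transcripts.values()
                if t.tclass == "mRNA"}

    @classmethod
    def from_files(cls, fasta: str | Path, annotation: str | Path,
                   top_genes: str | Path | None = None,
                   ires_genes: str | Path | None = None,
                   mito_rp_genes: str | Path | None = None) -> "ReferenceSet":
        """Build from a FASTA and an ORF annotation TSV.

        The annotation TSV has columns transcript_id, gene_symbol, species,
        class, cds_start, cds_end (0-based half-open; empty for non-mRNA).
        """
        seqs = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate transcript id {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
        ann = pd.read_csv(annotation, sep="\t",
                          dtype={"transcript_id": str, "gene_symbol": str})
        transcripts = {}
        for row in ann.to_dict("records"):
            tid = row["transcript_id"]
            if tid not in seqs:
                raise ValueError(f"annotation row without sequence: {tid}")
            if tid in transcripts:
                raise ValueError(f"duplicate annotation for {tid}")

            def _coord(v):
                return int(v) if pd.notna(v) and str(v) != "" else None

            transcripts[tid] = Transcript(
                tid, seqs[tid], row["species"], row["class"],
                row["gene_symbol"], _coord(row["cds_start"]),
                _coord(row["cds_end"]))
        unannotated = set(seqs) - set(transcripts)
        if unannotated:
            raise ValueError(f"sequences without annotation: {sorted(unannotated)[:5]}")
        return cls(transcripts,
                   load_gene_list(top_genes), load_gene_list(ires_genes),
                   load_gene_list(mito_rp_genes))


def load_gene_list(path: str | Path | None) -> frozenset:
    """Read a one-gene-per-line list; None or a missing value yields empty."""
    if path is None:
        return frozenset()
    lines = Path(path).read_text().split()
    return frozenset(g for g in lines if g)
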