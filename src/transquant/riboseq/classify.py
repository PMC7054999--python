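"""Hierarchical read classification.

Reads are assigned in priority order: human tRNA -> human rRNA -> the joint
human+yeast mRNA transcriptome -> unmapped.  A read whose transcriptome hits
are exclusively on yeast transcripts is classed ``yeast``; any human mRNA hit
makes it ``transcriptome``.  All transcriptome hits are retained, each with a
within-ORF flag (the read interval fully contained in the CDS, 0-based
half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

from .index import ExactMatchIndex
from .references import ReferenceSet

CATEGORIES = ("tRNA", "rRNA", "transcriptome", "yeast", "unmapped")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    length: int
    category: str
    hits: tuple  # of (transcript_id, start, within_orf)


class ReadClassifier:
    """Bundles the three per-class indexes and the classification rule."""

    def __init__(self, references: ReferenceSet, k: int = 15):
        self.references = references
        trna = {t.id: t.sequence for t in references.transcripts.values()
                if t.tclass == "tRNA"}
        rrna = {t.id: t.sequence for t in references.transcripts.values()
                if t.tclass == "rRNA"}
        mrna = {t.id: t.sequence for t in references.transcripts.values()
                if t.tclass == "mRNA"}
        self._trna = ExactMatchIndex(trna, k) if trna else None
        self._rrna = ExactMatchIndex(rrna, k) if rrna else None
        self._mrna = ExactMatchIndex(mrna, k) if mrna else None

    def classify(self, read_id: str, sequence: str) -> ReadAssignment:
        n = len(sequence)
        if self._trna is not None:
            hits = self._trna.query(sequence)
            if hits:
                return ReadAssignment(read_id, n, "tRNA",
                                      tuple((t, p, False) for t, p in hits))
        if self._rrna is not None:
            hits = self._rrna.query(sequence)
            if hits:
                return ReadAssignment(read_id, n, "rRNA",
                                      tuple((t, p, False) for t, p in hits))
        if self._mrna is not None:
            hits = self._mrna.query(sequence)
            if hits:
                annotated = []
                all_yeast = True
                for tid, pos in hits:
                    tx = self.references.transcripts[tid]
                    within = (tx.cds_start is not None
                              and tx.cds_start <= pos
                              and pos + n <= tx.cds_end)
                    annotated.append((tid, pos, within))
                    if tx.species != "yeast":
                        all_yeast = False
                category = "yeast" if all_yeast else "transcriptome"
                return ReadAssignment(read_id, n, category, tuple(annotated))
        return ReadAssignment(read_id, n, "unmapped", ())
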