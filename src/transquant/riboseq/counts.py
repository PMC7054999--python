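"""ORF-level gene counting with an explicit discard ledger.

A read counts toward gene g if and only if every one of its transcriptome
hits lies fully within an annotated CDS and all hit transcripts share the
gene symbol g — the strictest reading of "ORF-spanning".  Reads hitting two
or more gene symbols, or with any hit outside a CDS, are discarded and
tallied by reason.  The same rule applies to footprint and input samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .classify import ReadAssignment
from .references import ReferenceSet

DISCARD_REASONS = ("multi_gene", "outside_orf")


@dataclass
class CountTable:
    """Per-(gene, species) counts for one sample, plus the discard ledger."""

    counts: dict = field(default_factory=dict)   # gene_symbol -> int
    species: dict = field(default_factory=dict)  # gene_symbol -> species
    discards: dict = field(default_factory=lambda: dict.fromkeys(DISCARD_REASONS, 0))
    n_counted: int = 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype="int64").sort_index()

    def total(self, species: str | None = None) -> int:
        if species is None:
            return sum(self.counts.values())
        return sum(c for g, c in self.counts.items()
                   if self.species[g] == species)


def count_orf_reads(assignments: Iterable[ReadAssignment],
                    references: ReferenceSet) -> CountTable:
    """Apply the ORF counting rule to classified reads of one sample.

    Only ``transcriptome`` and ``yeast`` assignments are eligible; other
    categories pass through uncounted (they are accounted for in the
    classification totals, not the discard ledger).
    """
    table = CountTable()
    tx = references.transcripts
    for a in assignments:
        if a.category not in ("transcriptome", "yeast") or not a.hits:
            continue
        if any(not within for _, _, within in a.hits):
            table.discards["outside_orf"] += 1
            continue
        genes = {tx[tid].gene_symbol for tid, _, _ in a.hits}
        if len(genes) != 1:
            table.discards["multi_gene"] += 1
            continue
        gene = next(iter(genes))
        table.counts[gene] = table.counts.get(gene, 0) + 1
        table.species[gene] = tx[a.hits[0][0]].species
        table.n_counted += 1
    return table
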