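"""Ribo-Seq quality-control battery.

Per sample: fragment-length histograms per classification category,
reading-frame fractions of within-ORF footprint 5' ends (three values
summing to 1; strong frame-0 enrichment is the signature of genuine
ribosome footprints), metagene profiles of 5'-end positions around the
start and stop codons for reads of one configurable length, and a log-scale
Pearson correlation between replicate count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .classify import CATEGORIES, ReadAssignment
from .references import ReferenceSet


@dataclass
class QcSummary:
    length_hist: pd.DataFrame        # index length, columns category
    frame_fractions: np.ndarray      # 3 values summing to 1 (NaN if no reads)
    metagene_start: np.ndarray       # counts at offsets -window..window
    metagene_stop: np.ndarray
    window: int
    metagene_length: int
    n_frame_reads: int


class QcAccumulator:
    """Streaming accumulator so large samples never need stored assignments."""

    def __init__(self, references: ReferenceSet, metagene_length: int = 29,
                 window: int = 50):
        self.references = references
        self.metagene_length = metagene_length
        self.window = window
        self.length_counts: dict = {c: {} for c in CATEGORIES}
        self.frame_counts = np.zeros(3, dtype=np.int64)
        self.metagene_start = np.zeros(2 * window + 1, dtype=np.int64)
        self.metagene_stop = np.zeros(2 * window + 1, dtype=np.int64)

    def add(self, a: ReadAssignment) -> None:
        lc = self.length_counts[a.category]
        lc[a.length] = lc.get(a.length, 0) + 1
        if a.category in ("transcriptome", "yeast") and a.hits:
            tid, pos, within = a.hits[0]
            tx = self.references.transcripts[tid]
            if within and all(w for _, _, w in a.hits):
                self.frame_counts[(pos - tx.cds_start) % 3] += 1
            if a.length == self.metagene_length and tx.cds_start is not None:
                w = self.window
                off = pos - tx.cds_start
                if -w <= off <= w:
                    self.metagene_start[off + w] += 1
                off = pos - tx.cds_end
                if -w <= off <= w:
                    self.metagene_stop[off + w] += 1

    def summary(self) -> QcSummary:
        hist = pd.DataFrame(self.length_counts).fillna(0).astype(int).sort_index()
        total = self.frame_counts.sum()
        fractions = (self.frame_counts / total if total
                     else np.full(3, np.nan))
        return QcSummary(hist, fractions, self.metagene_start.copy(),
                         self.metagene_stop.copy(), self.window,
                         self.metagene_length, int(total))


def qc_summary(assignments: Iterable[ReadAssignment],
               references: ReferenceSet, metagene_length: int = 29,
               window: int = 50) -> QcSummary:
    acc = QcAccumulator(references, metagene_length, window)
    for a in assignments:
        acc.add(a)
    return acc.summary()


def replicate_correlation(counts_a: pd.Series, counts_b: pd.Series) -> float:
    """Pearson correlation of log-transformed replicate counts (pseudocount 1)."""
    union = counts_a.index.union(counts_b.index)
    a = np.log(counts_a.reindex(union, fill_value=0).to_numpy(dtype=float) + 1.0)
    b = np.log(counts_b.reindex(union, fill_value=0).to_numpy(dtype=float) + 1.0)
    if union.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r, _ = pearsonr(a, b)
    return float(r)
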