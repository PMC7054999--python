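"""End-to-end Ribo-Seq processing from FASTQ files to an RD analysis."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .classify import CATEGORIES, ReadClassifier
from .counts import CountTable
from .density import MeanRd, categorize_and_shift, compute_rd, mean_rd
from .normalize import spike_normalize
from .qc import QcAccumulator, QcSummary
from .references import ReferenceSet
from .trim import trim_read


@dataclass
class SampleCounts:
    """Everything retained from one FASTQ: counts, class totals, QC."""

    sample: str
    n_raw: int
    n_trimmed: int
    trim_rejects: dict
    class_totals: dict
    counts: CountTable
    qc: QcSummary


def process_fastq(path: str | Path, classifier: ReadClassifier,
                  adapter: str, n_random: int = 4, min_len: int = 15,
                  max_len: int = 45, metagene_length: int = 29,
                  sample: str | None = None) -> SampleCounts:
    """Trim, classify, count, and QC-accumulate one sample in a single pass."""
    refs = classifier.references
    counts = CountTable()
    qc = QcAccumulator(refs, metagene_length)
    class_totals = dict.fromkeys(CATEGORIES, 0)
    trim_rejects = {"too_short": 0, "too_long": 0}
    n_raw = n_trimmed = 0
    with open(path) as fh:
        for read_id, seq, _qual in FastqGeneralIterator(fh):
            n_raw += 1
            tr = trim_read(seq, adapter, n_random, min_len, max_len)
            if not tr.accepted:
                trim_rejects[tr.reason] += 1
                continue
            n_trimmed += 1
            a = classifier.classify(read_id, tr.sequence)
            class_totals[a.category] += 1
            qc.add(a)
            if a.category in ("transcriptome", "yeast"):
                # inline single-read counting to avoid storing assignments
                _count_one(a, counts, refs)
    return SampleCounts(sample or Path(path).stem, n_raw, n_trimmed,
                        trim_rejects, class_totals, counts, qc.summary())


def _count_one(a, table: CountTable, refs: ReferenceSet) -> None:
    """Single-read version of the ORF counting rule (see counts module)."""
    if any(not within for _, _, within in a.hits):
        table.discards["outside_orf"] += 1
        return
    genes = {refs.transcripts[tid].gene_symbol for tid, _, _ in a.hits}
    if len(genes) != 1:
        table.discards["multi_gene"] += 1
        return
    gene = next(iter(genes))
    table.counts[gene] = table.counts.get(gene, 0) + 1
    table.species[gene] = refs.transcripts[a.hits[0][0]].species
    table.n_counted += 1


@dataclass
class RdAnalysis:
    """Full result bundle of a two-condition footprint+input experiment."""

    samples: dict                 # (assay, condition) -> SampleCounts
    fp_factors: dict              # condition -> factor
    input_factors: dict
    rd_table: pd.DataFrame
    summary: MeanRd
    categories: pd.DataFrame
    normalization: str


def _library_size_factors(counts: Mapping[str, CountTable],
                          reference: str) -> dict[str, float]:
    totals = {c: t.total() for c, t in counts.items()}
    if any(v <= 0 for v in totals.values()):
        raise ValueError("zero counted reads in a sample")
    return {c: totals[reference] / v for c, v in totals.items()}


def run_pipeline(fastq: Mapping[tuple, str | Path],
                 references: ReferenceSet,
                 adapter: str,
                 control: str, treated: str,
                 n_random: int = 4, min_len: int = 15, max_len: int = 45,
                 min_input: int = 10,
                 normalization: Literal["spike", "library-size"] = "spike",
                 spike_input: bool = True,
                 metagene_length: int = 29) -> RdAnalysis:
    """Run the full chain on four FASTQ files.

    ``fastq`` maps (assay, condition) — assay in {"footprint", "input"},
    condition in {control, treated} — to file paths.  ``normalization``
    selects yeast spike-in factors (the method of record) or library-size
    factors (the deliberately blind alternative, for contrast).
    ``spike_input=False`` leaves input samples unnormalized (factor 1) while
    still spike-normalizing the footprints.
    """
    classifier = ReadClassifier(references, k=min_len)
    samples = {}
    for key, path in fastq.items():
        assay, condition = key
        samples[key] = process_fastq(path, classifier, adapter, n_random,
                                     min_len, max_len, metagene_length,
                                     sample=f"{assay}:{condition}")
    fp_counts = {c: samples[("footprint", c)].counts for c in (control, treated)}
    in_counts = {c: samples[("input", c)].counts for c in (control, treated)}
    if normalization == "spike":
        fp_factors = spike_normalize(fp_counts, control)
        input_factors = (spike_normalize(in_counts, control) if spike_input
                         else {control: 1.0, treated: 1.0})
    elif normalization == "library-size":
        fp_factors = _library_size_factors(fp_counts, control)
        input_factors = _library_size_factors(in_counts, control)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    rd_table = compute_rd(fp_counts, in_counts, fp_factors, input_factors,
                          control, treated, min_input)
    summary = mean_rd(rd_table,
                      {"control": fp_factors[control], "treated": fp_factors[treated]},
                      {"control": input_factors[control], "treated": input_factors[treated]})
    categories = categorize_and_shift(rd_table, references)
    return RdAnalysis(samples, fp_factors, input_factors, rd_table, summary,
                      categories, normalization)
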