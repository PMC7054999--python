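"""Ribosome density (RD), treatment fold changes, and category analysis.

RD of a human gene in a condition is its spike-normalized footprint count
divided by its spike-normalized ORF-spanning input count; delta RD is the
treated/control RD ratio.  Genes must reach a minimum input count in both
conditions to enter the table (no pseudocounts are used — underpowered genes
are filtered instead).  Summary estimators: the unweighted gene mean RD per
condition (primary), co-reported with the pooled aggregate
sum(footprints)/sum(input) over the same genes.  Category analysis labels
each gene 5'TOP > IRES > mito-RP > other (precedence order) and reports the
per-category median log2 delta RD plus a two-sample Kolmogorov-Smirnov
distance of each category's delta RD distribution against "other"
(descriptive, no p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .counts import CountTable
from .references import ReferenceSet

CATEGORY_PRECEDENCE = ("TOP", "IRES", "mito_rp", "other")


def compute_rd(fp_counts: Mapping[str, CountTable],
               input_counts: Mapping[str, CountTable],
               fp_factors: Mapping[str, float],
               input_factors: Mapping[str, float],
               control: str, treated: str,
               min_input: int = 10) -> pd.DataFrame:
    """Per-human-gene RD table over a control/treated condition pair.

    ``fp_counts`` and ``input_counts`` map condition name -> CountTable;
    the factor mappings carry the per-assay spike (or other) normalization.
    A gene passes the filter when its raw input count is >= ``min_input`` in
    both conditions and it has footprint counts in both.  Yeast genes are
    excluded from the table.
    """
    rows = []
    fp_c, fp_t = fp_counts[control], fp_counts[treated]
    in_c, in_t = input_counts[control], input_counts[treated]
    genes = sorted(set(fp_c.counts) | set(fp_t.counts)
                   | set(in_c.counts) | set(in_t.counts))
    for g in genes:
        species = (fp_c.species.get(g) or fp_t.species.get(g)
                   or in_c.species.get(g) or in_t.species.get(g))
        if species != "human":
            continue
        ic, it = in_c.counts.get(g, 0), in_t.counts.get(g, 0)
        fc, ft = fp_c.counts.get(g, 0), fp_t.counts.get(g, 0)
        passes = ic >= min_input and it >= min_input and fc > 0 and ft > 0
        rd_c = rd_t = delta = np.nan
        if passes:
            rd_c = (fc * fp_factors[control]) / (ic * input_factors[control])
            rd_t = (ft * fp_factors[treated]) / (it * input_factors[treated])
            delta = rd_t / rd_c
        rows.append((g, fc, ft, ic, it, passes, rd_c, rd_t, delta))
    table = pd.DataFrame(rows, columns=[
        "gene_symbol", "fp_control", "fp_treated", "input_control",
        "input_treated", "passes_filter", "rd_control", "rd_treated",
        "delta_rd"])
    if not table["passes_filter"].any():
        raise ValueError("no gene passes the minimum-input filter")
    return table


@dataclass(frozen=True)
class MeanRd:
    """Per-condition mean RD and fold change, gene-mean and pooled."""

    mean_rd_control: float
    mean_rd_treated: float
    fold_change: float            # treated/control of the gene-mean RD
    aggregate_rd_control: float   # sum(FP)/sum(input), spike-normalized
    aggregate_rd_treated: float
    aggregate_fold_change: float
    n_genes: int

    @property
    def fold_reduction(self) -> float:
        """Control/treated ratio (>1 when treatment suppresses translation)."""
        return 1.0 / self.fold_change


def mean_rd(rd_table: pd.DataFrame,
            fp_factors: Mapping[str, float] | None = None,
            input_factors: Mapping[str, float] | None = None,
            control: str = "control", treated: str = "treated") -> MeanRd:
    """Summarize an RD table over its passing genes.

    The unweighted gene mean is the primary estimator; the pooled aggregate
    sum(FP)/sum(input) (both spike-normalized, over the same passing genes)
    is co-reported.  When factor mappings are omitted the aggregate uses the
    raw counts (factors of 1).
    """
    passing = rd_table[rd_table["passes_filter"]]
    if passing.empty:
        raise ValueError("empty RD table")
    fpc = fp_factors[control] if fp_factors else 1.0
    fpt = fp_factors[treated] if fp_factors else 1.0
    inc = input_factors[control] if input_factors else 1.0
    int_ = input_factors[treated] if input_factors else 1.0
    agg_c = passing["fp_control"].sum() * fpc / (passing["input_control"].sum() * inc)
    agg_t = passing["fp_treated"].sum() * fpt / (passing["input_treated"].sum() * int_)
    mc = float(passing["rd_control"].mean())
    mt = float(passing["rd_treated"].mean())
    return MeanRd(mc, mt, mt / mc, float(agg_c), float(agg_t),
                  float(agg_t / agg_c), len(passing))


def categorize_genes(genes, references: ReferenceSet) -> pd.Series:
    """Label genes TOP > IRES > mito-RP > other (first match wins)."""
    labels = []
    for g in genes:
        if g in references.top_genes:
            labels.append("TOP")
        elif g in references.ires_genes:
            labels.append("IRES")
        elif g in references.mito_rp_genes:
            labels.append("mito_rp")
        else:
            labels.append("other")
    return pd.Series(labels, index=pd.Index(genes, name="gene_symbol"),
                     name="category")


def categorize_and_shift(rd_table: pd.DataFrame,
                         references: ReferenceSet) -> pd.DataFrame:
    """Per-category delta RD summary.

    Returns one row per category present among passing genes: gene count,
    median log2 delta RD, and the KS distance of the category's delta RD
    distribution against the "other" category (NaN when either side is
    empty).
    """
    passing = rd_table[rd_table["passes_filter"]].copy()
    passing["category"] = categorize_genes(passing["gene_symbol"],
                                           references).to_numpy()
    passing["log2_delta_rd"] = np.log2(passing["delta_rd"])
    other = passing.loc[passing["category"] == "other", "delta_rd"].to_numpy()
    rows = []
    for cat in CATEGORY_PRECEDENCE:
        sub = passing[passing["category"] == cat]
        if sub.empty:
            rows.append((cat, 0, np.nan, np.nan))
            continue
        ks = np.nan
        if cat != "other" and other.size > 0:
            ks = float(ks_2samp(sub["delta_rd"].to_numpy(), other).statistic)
        elif cat == "other":
            ks = 0.0
        rows.append((cat, len(sub), float(sub["log2_delta_rd"].median()), ks))
    return pd.DataFrame(rows, columns=["category", "n_genes",
                                       "median_log2_delta_rd",
                                       "ks_distance_vs_other"])
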