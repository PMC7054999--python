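"""Stress-granule (SG) screen scoring and candidate calling.

A kinase/phosphatase knockdown screen images cells transfected with four
independent siRNAs per gene and counts, per well, the number of cells
containing stress granules.  Each gene receives an SG score:

    score = (sum of SG-containing cells over all of the gene's siRNAs)
            x (number of siRNAs "causing" SGs)

so that both the strength and the reproducibility of the phenotype enter the
statistic.  A gene is a screen candidate when its score exceeds 10 with two
or more causing siRNAs, or exceeds 40 with a single causing siRNA (strict
inequalities).

An siRNA "causes" SGs when its cell count reaches ``causing_min`` (default 1,
i.e. any SG-containing cell); microscopes differ in their false-positive
behaviour, so the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ScreenThresholds",
    "SgScore",
    "compute_sg_score",
    "call_candidate",
    "score_table",
    "summarize_screen",
    "read_screen_table",
    "load_mapped_table",
]


@dataclass(frozen=True)
class ScreenThresholds:
    causing_min: int = 1
    multi_sirna_score: float = 10.0
    multi_sirna_min_causing: int = 2
    single_sirna_score: float = 40.0

    def __post_init__(self) -> None:
        if min(self.causing_min, self.multi_sirna_score,
               self.multi_sirna_min_causing, self.single_sirna_score) <= 0:
            raise ValueError("all screen thresholds must be positive")


@dataclass(frozen=True)
class SgScore:
    gene_id: str
    sum_sg_cells: int
    n_causing: int
    score: int
    is_candidate: bool


def call_candidate(score: float, n_causing: int,
                   thresholds: ScreenThresholds = ScreenThresholds()) -> bool:
    """Candidate rule: score > 10 with >= 2 causing siRNAs, or > 40 with 1.

    Comparisons are strict, so boundary scores are not candidates.
    """
    if n_causing >= thresholds.multi_sirna_min_causing:
        return score > thresholds.multi_sirna_score
    if n_causing == 1:
        return score > thresholds.single_sirna_score
    return False


def compute_sg_score(gene_id: str, counts: Sequence[int],
                     thresholds: ScreenThresholds = ScreenThresholds()) -> SgScore:
    """Score one gene from the per-siRNA SG-containing-cell counts."""
    if len(counts) == 0:
        raise ValueError(f"no observations for gene {gene_id}")
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError(f"negative SG cell count for gene {gene_id}")
    total = sum(counts)
    n_causing = sum(c >= thresholds.causing_min for c in counts)
    score = total * n_causing
    return SgScore(gene_id, total, n_causing, score,
                   call_candidate(score, n_causing, thresholds))


def score_table(observations: pd.DataFrame,
                thresholds: ScreenThresholds = ScreenThresholds(),
                per_1000_cells: int | None = None) -> pd.DataFrame:
    """Score every gene in a long observation table.

    ``observations`` needs columns ``gene_id``, ``sirna_index`` and
    ``sg_cell_count``; replicate wells for the same (gene, siRNA) are summed
    before scoring, because the score is defined on totals over all images of
    a gene's siRNAs.  ``per_1000_cells`` optionally rescales counts to a
    common seeded-cell number (off by default; the published scores used raw
    counts); it requires a ``cells_seeded`` column.
    """
    required = {"gene_id", "sirna_index", "sg_cell_count"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table lacks columns {sorted(missing)}")
    if (observations["sg_cell_count"] < 0).any():
        raise ValueError("negative SG cell counts")
    obs = observations.copy()
    if per_1000_cells is not None:
        obs["sg_cell_count"] = (
            obs["sg_cell_count"] * 1000.0 / obs["cells_seeded"]).round().astype(int)
    per_sirna = (obs.groupby(["gene_id", "sirna_index"], sort=True)["sg_cell_count"]
                 .sum().reset_index())
    rows = []
    for gene_id, grp in per_sirna.groupby("gene_id", sort=True):
        s = compute_sg_score(str(gene_id), grp["sg_cell_count"].tolist(), thresholds)
        rows.append((s.gene_id, s.sum_sg_cells, s.n_causing, s.score, s.is_candidate))
    out = pd.DataFrame(rows, columns=["gene_id", "sum_sg_cells", "n_causing",
                                      "score", "is_candidate"])
    return out


def summarize_screen(scores: pd.DataFrame,
                     control_genes: Iterable[str] = (),
                     class_map: Mapping[str, str] | None = None):
    """Rank scores and report the control mean SG score.

    Returns ``(ranked, control_mean, candidate_counts)``.  Ranking is by
    descending score with ties broken lexicographically by gene_id, so the
    table is deterministic.  ``class_map`` (gene_id -> class, e.g.
    kinase/phosphatase) adds a class column and per-class candidate counts.
    """
    if scores.empty:
        raise ValueError("empty score table")
    control_genes = list(control_genes)
    unknown = set(control_genes) - set(scores["gene_id"])
    if unknown:
        raise ValueError(f"unknown control gene ids: {sorted(unknown)}")
    ranked = scores.sort_values(["score", "gene_id"],
                                ascending=[False, True]).reset_index(drop=True)
    control_mean = (
        float(scores.set_index("gene_id").loc[control_genes, "score"].mean())
        if control_genes else float("nan"))
    candidate_counts: dict[str, int] = {}
    if class_map is not None:
        ranked = ranked.assign(
            gene_class=[class_map.get(g, "unknown") for g in ranked["gene_id"]])
        candidate_counts = (ranked[ranked["is_candidate"]]
                            .groupby("gene_class")["gene_id"].count().to_dict())
    else:
        candidate_counts = {"all": int(ranked["is_candidate"].sum())}
    return ranked, control_mean, candidate_counts


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of per-siRNA observations."""
    df = pd.read_csv(path, sep="\t")
    return df


def load_mapped_table(path: str | Path, column_map: Mapping[str, str],
                      sep: str = "\t") -> pd.DataFrame:
    """Load an external score/observation table via a column-name mapping.

    ``column_map`` maps our canonical names (e.g. ``gene_id``, ``score``,
    ``n_causing``) to the column names used in the external file, so deposited
    supplementary tables can be ingested for validation without reformatting.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [v for v in column_map.values() if v not in df.columns]
    if missing:
        raise ValueError(f"mapped columns not in file: {missing}")
    return df.rename(columns={v: k for k, v in column_map.items()})[
        list(column_map.keys())]
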