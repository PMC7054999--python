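"""SILAC phosphoproteomics ratio orientation, normalization, and hit calling.

In a label-swap SILAC design the treated condition is heavy-labeled in one
replicate and light-labeled in the repeat, so the raw heavy/light (H/L) ratio
must first be oriented into a treated/control ratio (reciprocal when treated
was light).  Phosphopeptide ratios are then normalized to the oriented ratio
of the corresponding total protein, which cancels abundance changes of the
parent protein and isolates the change in phosphorylation stoichiometry.
Treatment-sensitive sites are called when the normalized ratio clears a fold
cutoff concordantly in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "orient_ratio",
    "normalize_to_protein",
    "normalize_table",
    "replicate_concordance",
    "call_sensitive_sites",
    "PhosphoHit",
]

Orientation = Literal["heavy", "light"]


@dataclass(frozen=True)
class PhosphoHit:
    site_id: str
    geo_mean_ratio: float
    direction: Literal["down", "up"]
    n_replicates: int


def orient_ratio(hl_ratio: float, treated_label: Orientation) -> float:
    """Turn a raw H/L ratio into a treated/control ratio.

    H/L is returned as-is when the treated condition carried the heavy label,
    and inverted when the treated condition was light.
    """
    if not hl_ratio > 0:
        raise ValueError(f"H/L ratio must be positive, got {hl_ratio}")
    if treated_label == "heavy":
        return float(hl_ratio)
    if treated_label == "light":
        return 1.0 / float(hl_ratio)
    raise ValueError(f"unknown label orientation {treated_label!r}")


def normalize_to_protein(phospho_ratio: float,
                         protein_ratio: float | None) -> tuple[float, bool]:
    """Divide the oriented phospho ratio by the oriented total-protein ratio.

    Returns ``(ratio, normalized_flag)``; when no protein ratio is available
    the raw phospho ratio is kept with the flag set to False so the site stays
    in the output but can be excluded from normalized plots.
    """
    if not phospho_ratio > 0:
        raise ValueError("phospho ratio must be positive")
    if protein_ratio is None or (isinstance(protein_ratio, float)
                                 and np.isnan(protein_ratio)):
        return float(phospho_ratio), False
    if not protein_ratio > 0:
        raise ValueError("protein ratio must be positive")
    return float(phospho_ratio) / float(protein_ratio), True


def normalize_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Orient and protein-normalize a long SILAC table.

    Expected columns: ``site_id``, ``replicate``, ``phospho_HL``,
    ``protein_HL`` (may be NaN), ``treated_label`` ({heavy, light}).  Multiple
    phosphopeptide rows for the same (site, replicate) are aggregated by the
    median of their H/L ratios before orientation.  Returns one row per
    (site, replicate) with ``oriented_phospho``, ``oriented_protein``,
    ``normalized_ratio`` and ``normalized`` flag.
    """
    required = {"site_id", "replicate", "phospho_HL", "protein_HL", "treated_label"}
    if not required <= set(measurements.columns):
        raise ValueError(f"SILAC table needs columns {sorted(required)}")
    agg = (measurements.groupby(["site_id", "replicate"], sort=True)
           .agg(phospho_HL=("phospho_HL", "median"),
                protein_HL=("protein_HL", "median"),
                treated_label=("treated_label", "first"))
           .reset_index())
    rows = []
    for rec in agg.itertuples(index=False):
        phospho = orient_ratio(rec.phospho_HL, rec.treated_label)
        protein = (orient_ratio(rec.protein_HL, rec.treated_label)
                   if pd.notna(rec.protein_HL) else None)
        normalized, flag = normalize_to_protein(phospho, protein)
        rows.append((rec.site_id, rec.replicate, phospho,
                     protein if protein is not None else np.nan,
                     normalized, flag))
    return pd.DataFrame(rows, columns=["site_id", "replicate", "oriented_phospho",
                                       "oriented_protein", "normalized_ratio",
                                       "normalized"])


def replicate_concordance(normalized: pd.DataFrame,
                          replicates: tuple = None,
                          normalized_only: bool = True):
    """Pair per-site normalized ratios across two replicates.

    Returns ``(paired_df, log_correlation)`` where ``paired_df`` has one row
    per site present in both replicates (columns ``n1``, ``n2``) and the
    correlation is Pearson's r of the log ratios (NaN when fewer than two
    shared sites make it undefined).
    """
    reps = sorted(normalized["replicate"].unique()) if replicates is None \
        else list(replicates)
    if len(reps) < 2:
        raise ValueError("need at least two replicates")
    table = normalized
    if normalized_only:
        table = table[table["normalized"]]
    wide = table.pivot_table(index="site_id", columns="replicate",
                             values="normalized_ratio").dropna(subset=reps[:2])
    paired = wide[reps[:2]].rename(columns={reps[0]: "n1", reps[1]: "n2"})
    if len(paired) < 2:
        return paired, float("nan")
    r, _ = pearsonr(np.log(paired["n1"]), np.log(paired["n2"]))
    return paired, float(r)


def call_sensitive_sites(normalized: pd.DataFrame,
                         fold_cut: float = 2.0) -> list[PhosphoHit]:
    """Call treatment-sensitive sites from the normalized ratio table.

    A site is a down-hit when its normalized ratio is <= 1/fold_cut in every
    replicate in which it was measured, and an up-hit symmetrically at
    >= fold_cut; discordant sites are not hits.  The geometric mean across
    replicates is reported.  The fold cutoff and the all-replicate concordance
    requirement are quantification choices of this package.
    """
    if fold_cut <= 0:
        raise ValueError("fold_cut must be positive")
    hits = []
    for site_id, grp in normalized.groupby("site_id", sort=True):
        ratios = grp["normalized_ratio"].to_numpy(dtype=float)
        if ratios.size == 0:
            continue
        geo = float(np.exp(np.mean(np.log(ratios))))
        down = bool(np.all(ratios <= 1.0 / fold_cut))
        up = bool(np.all(ratios >= fold_cut))
        if down and up:  # only at fold_cut <= 1 with ratios pinned to 1
            continue
        if down:
            hits.append(PhosphoHit(str(site_id), geo, "down", ratios.size))
        elif up:
            hits.append(PhosphoHit(str(site_id), geo, "up", ratios.size))
    return hits
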