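"""Simulated label-swap SILAC phosphoproteomics tables.

Each site has a true phospho effect (treated/control change in
phosphopeptide abundance beyond the protein-level change): 1 for unaffected
sites, ``true_phospho_effect`` for the treatment-dependent fraction.  A
site-specific protein-level effect (lognormal) multiplies both the
phosphopeptide and the total-protein ratio, so protein normalization must
cancel it.  Replicates follow the swap design: in replicate 1 the treated
condition carries the heavy label, in replicate 2 the light label, so the raw
H/L ratio of replicate 2 is the reciprocal of the oriented ratio.
Measurement noise is lognormal (Gaussian on the log scale), independent
between the phospho and protein measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SilacSimConfig:
    n_sites: int = 1000
    cdk1_dependent_fraction: float = 0.1
    true_phospho_effect: float = 0.5
    protein_effect_sd: float = 0.2     # log scale
    measurement_noise_sd: float = 0.1  # log scale
    label_orientation: Sequence[str] = ("heavy", "light")  # treated label per replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.true_phospho_effect <= 0:
            raise ValueError("true_phospho_effect must be positive")
        if not 0.0 <= self.cdk1_dependent_fraction <= 1.0:
            raise ValueError("cdk1_dependent_fraction must be a probability")
        if any(o not in ("heavy", "light") for o in self.label_orientation):
            raise ValueError("orientations must be 'heavy' or 'light'")


def gen_silac(config: SilacSimConfig):
    """Generate (long SILAC table, truth).

    The table has one row per (site, replicate) with phospho and protein H/L
    ratios and the replicate's treated-label orientation.  Truth records each
    site's true phospho effect and protein effect.
    """
    from . import SyntheticTruth

    rng = np.random.default_rng(config.seed)
    site_ids = [f"SITE{i:05d}" for i in range(config.n_sites)]
    dependent = rng.random(config.n_sites) < config.cdk1_dependent_fraction
    phospho_effect = np.where(dependent, config.true_phospho_effect, 1.0)
    protein_effect = np.exp(rng.normal(0.0, config.protein_effect_sd,
                                       config.n_sites))
    rows = []
    for r, orientation in enumerate(config.label_orientation, start=1):
        noise_p = np.exp(rng.normal(0.0, config.measurement_noise_sd,
                                    config.n_sites))
        noise_t = np.exp(rng.normal(0.0, config.measurement_noise_sd,
                                    config.n_sites))
        oriented_phospho = phospho_effect * protein_effect * noise_p
        oriented_protein = protein_effect * noise_t
        if orientation == "heavy":
            hl_p, hl_t = oriented_phospho, oriented_protein
        else:
            hl_p, hl_t = 1.0 / oriented_phospho, 1.0 / oriented_protein
        for i, site in enumerate(site_ids):
            rows.append((site, r, float(hl_p[i]), float(hl_t[i]), orientation))
    table = pd.DataFrame(rows, columns=["site_id", "replicate", "phospho_HL",
                                        "protein_HL", "treated_label"])
    truth = SyntheticTruth(
        assay="silac",
        params={"config": {**config.__dict__,
                           "label_orientation": list(config.label_orientation)}},
        tables={"sites": pd.DataFrame({
            "site_id": site_ids,
            "is_dependent": dependent,
            "true_phospho_effect": phospho_effect,
            "protein_effect": protein_effect,
        })},
    )
    return table, truth
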