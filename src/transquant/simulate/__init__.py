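"""Synthetic datasets with machine-readable ground truth for every assay.

Each generator is a pure function of its configuration and seed: running it
twice with the same arguments yields bit-identical outputs.  Alongside every
simulated dataset a :class:`SyntheticTruth` records the generating parameters
of every emitted entity (hit genes, peak areas, per-gene ribosome densities,
per-site phospho effects, per-cell intensities), so the analysis modules can
be tested for parameter recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .screen import ScreenSimConfig, gen_screen
from .trace import PeakSpec, TraceSimConfig, gen_trace
from .silac import SilacSimConfig, gen_silac
from .images import ImageSimConfig, gen_images
from .riboseq import RiboSimConfig, gen_riboseq, riboseq_preset

__all__ = [
    "SyntheticTruth",
    "ScreenSimConfig", "gen_screen",
    "PeakSpec", "TraceSimConfig", "gen_trace",
    "SilacSimConfig", "gen_silac",
    "ImageSimConfig", "gen_images",
    "RiboSimConfig", "gen_riboseq", "riboseq_preset",
]


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted alongside a simulated dataset."""

    assay: str
    params: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame

    def write(self, directory: str | Path) -> None:
        """Write params as JSON and every truth table as TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / f"truth_{self.assay}_params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)
        for name, table in self.tables.items():
            table.to_csv(directory / f"truth_{self.assay}_{name}.tsv",
                         sep="\t", index=False)

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]
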