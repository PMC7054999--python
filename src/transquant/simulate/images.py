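"""Simulated three-channel immunofluorescence fields.

Each cell is a pair of concentric disks: a bright nucleus in the Hoechst
channel and a larger cell body in the eIF3B channel.  The puromycin channel
paints each cell body at the condition's mean intensity times a per-cell
lognormal factor (cell-to-cell variability of synthesis rates), over a
constant background; all channels receive additive Gaussian noise.  Cells are
placed by rejection sampling so cell disks never overlap; the placement
fails with an error when the field cannot accommodate the requested number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PlacementError(RuntimeError):
    """Raised when n_cells cannot be placed without overlap."""


@dataclass(frozen=True)
class ImageSimConfig:
    image_shape: tuple = (256, 256)
    n_cells: int = 25
    nucleus_radius: tuple = (5, 8)
    cell_radius: tuple = (12, 18)
    puromycin_mean: float = 1000.0
    cell_lognormal_sd: float = 0.1    # log scale, per-cell factor
    noise_sd: float = 10.0
    background: float = 100.0
    hoechst_level: float = 2000.0
    eif3b_level: float = 800.0
    margin: int = 4                   # keep cells off the border
    max_attempts: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if max(self.cell_radius) >= min(self.image_shape) / 4:
            raise ValueError("cell radius too large for the image")
        if self.puromycin_mean < self.background:
            raise ValueError("puromycin_mean must be >= background")
        if self.nucleus_radius[0] > self.nucleus_radius[1] \
                or self.cell_radius[0] > self.cell_radius[1]:
            raise ValueError("radius ranges must be (low, high)")


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def gen_images(config: ImageSimConfig):
    """Generate ((hoechst, eif3b, puromycin), truth) for one condition.

    Truth lists each cell's center, radii, and true mean puromycin intensity.
    """
    from . import SyntheticTruth

    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    centers: list[tuple[int, int]] = []
    radii: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < config.n_cells:
        if attempts >= config.max_attempts:
            raise PlacementError(
                f"could not place {config.n_cells} cells in {attempts} attempts")
        attempts += 1
        rc = int(rng.integers(config.cell_radius[0], config.cell_radius[1] + 1))
        rn = int(rng.integers(config.nucleus_radius[0],
                              config.nucleus_radius[1] + 1))
        lo = rc + config.margin
        cy = int(rng.integers(lo, h - lo))
        cx = int(rng.integers(lo, w - lo))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (rc + r + 2) ** 2
               for (y, x), (r, _) in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append((rc, rn))

    hoechst = np.full((h, w), config.background, dtype=float)
    eif3b = np.full((h, w), config.background, dtype=float)
    puromycin = np.full((h, w), config.background, dtype=float)
    cell_factor = np.exp(rng.normal(0.0, config.cell_lognormal_sd,
                                    config.n_cells))
    truth_rows = []
    for i, ((cy, cx), (rc, rn)) in enumerate(zip(centers, radii)):
        cell = _disk_mask((h, w), cy, cx, rc)
        nucleus = _disk_mask((h, w), cy, cx, rn)
        eif3b[cell] = config.eif3b_level
        hoechst[nucleus] = config.hoechst_level
        true_mean = config.puromycin_mean * float(cell_factor[i])
        puromycin[cell] = true_mean
        truth_rows.append((i + 1, cy, cx, rc, rn, true_mean))
    if config.noise_sd > 0:
        hoechst += rng.normal(0, config.noise_sd, (h, w))
        eif3b += rng.normal(0, config.noise_sd, (h, w))
        puromycin += rng.normal(0, config.noise_sd, (h, w))
    hoechst = np.clip(hoechst, 0, None)
    eif3b = np.clip(eif3b, 0, None)
    puromycin = np.clip(puromycin, 0, None)
    truth = SyntheticTruth(
        assay="images",
        params={"n_cells": config.n_cells,
                "puromycin_mean": config.puromycin_mean,
                "background": config.background},
        tables={"cells": pd.DataFrame(
            truth_rows, columns=["cell", "center_y", "center_x", "cell_radius",
                                 "nucleus_radius", "true_mean_puromycin"])},
    )
    return (hoechst, eif3b, puromycin), truth
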