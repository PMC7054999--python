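"""Between-sample normalization: yeast spike-in factors and median-of-ratios.

Spike-in normalization: equal amounts of yeast lysate were added to every
sample, so the yeast ORF read total is proportional to each library's
capture efficiency.  Scaling every sample so its yeast total matches the
reference sample's makes human counts comparable on an absolute scale —
unlike library-size scaling, which erases genuine global shifts.

Median-of-ratios: the classical size-factor estimator for count matrices —
for each sample, the median over genes (nonzero in all samples) of the
gene's count divided by its across-sample geometric mean.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountTable


class SpikeInError(ValueError):
    """Raised when a sample has no yeast ORF reads to normalize by."""


def spike_normalize(counts_by_sample: Mapping[str, CountTable],
                    reference_sample: str) -> dict[str, float]:
    """Per-sample scale factors equalizing yeast ORF totals to the reference.

    factor_s = yeast_total(reference) / yeast_total(s); the reference factor
    is exactly 1.  Footprint and input assays are normalized separately by
    calling this once per assay.  Factors are independent of human counts.
    """
    if reference_sample not in counts_by_sample:
        raise ValueError(f"reference sample {reference_sample!r} missing")
    totals = {s: t.total("yeast") for s, t in counts_by_sample.items()}
    if any(v <= 0 for v in totals.values()):
        bad = [s for s, v in totals.items() if v <= 0]
        raise SpikeInError(f"zero yeast ORF counts in samples {bad}")
    ref = totals[reference_sample]
    return {s: ref / v for s, v in totals.items()}


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a genes x samples count matrix.

    s_j = median over genes g (with k_g,j' > 0 in every sample j') of
    k_g,j / (prod_j' k_g,j')^(1/m).  Factors are reported as computed, with
    no rescaling.
    """
    mat = counts.to_numpy(dtype=float)
    keep = (mat > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no gene has nonzero counts in every sample")
    mat = mat[keep]
    log_geo = np.log(mat).mean(axis=1, keepdims=True)
    factors = np.median(np.exp(np.log(mat) - log_geo), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")
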