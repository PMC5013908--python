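"""FDR Inverse Quantile Transformation (FIQT).

Winner's curse makes the most significant Z-scores of a genome scan
overestimate their true means (noncentralities).  Multiple-testing adjustment
on the p-value scale shrinks p-values toward one — the image of a zero
Z-score — so, by the invariance principle, an MTA back-transformed to the
Z-scale is a winner's-curse adjustment.  FIQT:

1. computes two-sided p-values ``p_i = 2*Phi(-|X_i|)``,
2. adjusts them for multiple testing (Benjamini-Hochberg FDR q-values by
   default),
3. back-transforms: ``X*_i = sign(X_i) * Phi^-1(1 - q_i/2)``.

Since q >= p always, |X*| <= |X|: the transform only shrinks toward zero.
The quantile is evaluated in log space, so scans with |Z| up to ~37 survive
the round trip without overflow.

Inputs are assumed variance-1 (X_i ~ N(mu_i, 1)); apply any genomic-control
rescaling before calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .mta import MTA_METHODS, adjust_pvalues

__all__ = ["NoncentralityEstimates", "fiqt", "fiqt_with_mta", "mle_estimate"]


@dataclass(frozen=True)
class NoncentralityEstimates:
    """Per-variant estimates of Z-score true means, aligned to a scan.

    ``method`` labels the estimator ("FIQT", "EB-1", "EB-100", "TA", "MLE",
    ...); ``values`` holds one estimate per input statistic (NaN where the
    input was missing).
    """

    method: str
    values: np.ndarray

    def __len__(self) -> int:
        return self.values.size


def _back_transform(q: np.ndarray) -> np.ndarray:
    """|Z| scale image of adjusted p-values: Phi^-1(1 - q/2), in log space."""
    return -special.ndtri_exp(np.log(q) - math.log(2.0))


def fiqt_with_mta(z, mta_method: str = "fdr", label: str | None = None) -> NoncentralityEstimates:
    """FIQT with a chosen multiple-testing adjustment.

    With ``mta_method="fdr"`` this is :func:`fiqt`.  Missing (NaN) statistics
    are excluded from the adjustment pool — including them would inflate the
    test count k — and receive NaN estimates.
    """
    if mta_method not in MTA_METHODS:
        raise ValueError(f"unknown MTA method {mta_method!r}; choose from {MTA_METHODS}")
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z must be a non-empty 1-D vector")
    missing = np.isnan(z)
    if np.any(np.isinf(z)):
        bad = np.flatnonzero(np.isinf(z))[:5]
        raise ValueError(f"non-finite z at indices {bad.tolist()}")

    out = np.full(z.shape, np.nan)
    zz = z[~missing]
    if zz.size:
        p = 2.0 * stats.norm.sf(np.abs(zz))
        # |z| beyond ~38.4 underflows the two-sided p; clamp to the smallest
        # positive normal double so the adjustment pool stays in (0, 1]
        p = np.maximum(p, np.finfo(float).tiny)
        q = adjust_pvalues(p, mta_method).values
        est = _back_transform(q)
        sign = np.sign(zz)
        sign[sign == 0] = 1.0  # z = 0 has q = 1 hence estimate 0 regardless
        out[~missing] = sign * est
    if label is None:
        label = "FIQT" if mta_method == "fdr" else f"FIQT-{mta_method}"
    return NoncentralityEstimates(method=label, values=out)


def fiqt(z) -> NoncentralityEstimates:
    """FDR Inverse Quantile Transformation of a Z-score vector."""
    return fiqt_with_mta(z, "fdr", label="FIQT")


def mle_estimate(z) -> NoncentralityEstimates:
    """Naive maximum-likelihood estimate: the observed statistics themselves."""
    return NoncentralityEstimates(method="MLE", values=np.asarray(z, dtype=float).copy())
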