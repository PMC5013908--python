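"""Multiple-testing adjustment (MTA) of p-values.

Benjamini-Hochberg FDR q-values are the default adjustment feeding the
inverse-quantile back-transform; Bonferroni and Holm family-wise adjustments
are available as drop-in alternatives.  All three are thin, validated wrappers
over :func:`statsmodels.stats.multitest.multipletests`.

Note the Bonferroni adjusted value is ``min(k*p, 1)`` — the clip is at one
from above, as in every standard implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["QValues", "bh_qvalues", "bonferroni_qvalues", "holm_qvalues", "adjust_pvalues", "MTA_METHODS"]

_SM_METHOD = {"fdr": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}
MTA_METHODS = tuple(_SM_METHOD)


@dataclass(frozen=True)
class QValues:
    """Adjusted p-values aligned to the input vector.

    Invariants: every q >= its source p, all q <= 1, and for the FDR
    step-up adjustment the q sequence is non-decreasing in sorted-p order.
    """

    values: np.ndarray
    method: str
    k: int

    def __len__(self) -> int:
        return self.k


def _validate(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = np.flatnonzero(~np.isfinite(p) | (p <= 0) | (p > 1))[:5]
        raise ValueError(f"p-values outside (0, 1] at indices {bad.tolist()}")
    return p


def adjust_pvalues(p, method: str = "fdr") -> QValues:
    """Adjust a vector of p-values with the named MTA method.

    ``method`` is one of ``"fdr"`` (Benjamini-Hochberg step-up),
    ``"bonferroni"`` or ``"holm"`` (step-down).
    """
    if method not in _SM_METHOD:
        raise ValueError(f"unknown MTA method {method!r}; choose from {MTA_METHODS}")
    p = _validate(p)
    q = multipletests(p, alpha=0.05, method=_SM_METHOD[method])[1]
    return QValues(values=np.asarray(q, dtype=float), method=method, k=p.size)


def bh_qvalues(p) -> QValues:
    """Benjamini-Hochberg FDR q-values: q_(i) = min_{j>=i} min(k*p_(j)/j, 1)."""
    return adjust_pvalues(p, "fdr")


def bonferroni_qvalues(p) -> QValues:
    """Bonferroni adjustment q_i = min(k*p_i, 1)."""
    return adjust_pvalues(p, "bonferroni")


def holm_qvalues(p) -> QValues:
    """Holm step-down adjustment q_(i) = max_{j<=i} min((k-j+1)*p_(j), 1)."""
    return adjust_pvalues(p, "holm")
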