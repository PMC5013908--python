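"""Reading, writing and scale conversion of GWAS summary statistics.

A genome scan reports, per variant, some subset of {Z, beta/SE, OR/SE,
P + effect direction}.  This module loads such delimited-text tables into a
:class:`ScanStatistics` container with both the Z-score ``X_i`` and the
two-sided p-value ``p_i`` populated, deriving whichever is missing, and
converts winner's-curse adjusted Z-scores back to the effect scale
(``ln(OR)* = sigma_hat * X*``).

Conventions: two-sided p-values ``p = 2*Phi(-|z|)``; 1-based base-pair
coordinates; quantiles evaluated in log space so that any representable
positive p yields a finite Z.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ScanStatistics",
    "LoadReport",
    "ConfigurationError",
    "InputError",
    "read_sumstats",
    "z_from_effect_se",
    "z_from_pvalue_sign",
    "pvalue_from_z",
    "adjusted_effect_from_z",
    "write_adjusted",
]

# p/z consistency check threshold: relative |p - 2*Phi(-|z|)| / p
_CONSISTENCY_RTOL = 1e-3

# logical column names the loader understands
LOGICAL_COLUMNS = ("snp", "chrom", "pos", "z", "beta", "se", "or", "p", "direction")


class ConfigurationError(ValueError):
    """A column mapping or option is invalid."""


class InputError(ValueError):
    """An input table is unusable (e.g. zero parseable rows)."""


def z_from_effect_se(effect: float, se: float) -> float:
    """Z-score from an effect estimate (beta or ln OR) and its standard error.

    ``X = ln(OR)/sigma_hat`` for odds-ratio scale input; ``X = beta/SE``
    for regression coefficients.
    """
    if np.any(np.asarray(se) <= 0):
        raise ValueError(f"standard error must be positive, got {se}")
    return effect / se


def z_from_pvalue_sign(p, sign):
    """Signed Z-score from a two-sided p-value and an effect direction.

    Returns ``sign * Phi^-1(1 - p/2)``, evaluated via the log-space inverse
    normal CDF (`scipy.special.ndtri_exp`) so that p-values down to the
    smallest representable positive double give a finite Z (~38.5) instead
    of overflowing.
    """
    p = np.asarray(p, dtype=float)
    sign = np.asarray(sign, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    # Phi^-1(1 - p/2) = -Phi^-1(p/2) = -ndtri_exp(log p - log 2)
    z = -special.ndtri_exp(np.log(p) - math.log(2.0))
    out = np.sign(sign) * z
    # sign 0 is treated as +1; result is only nonzero when p < 1 anyway
    out = np.where(np.sign(sign) == 0, z, out)
    if out.ndim == 0:
        return float(out)
    return out


def pvalue_from_z(z):
    """Two-sided p-value ``p = 2*Phi(-|z|)`` of a Z-score."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if p.ndim == 0:
        return float(p)
    return p


def adjusted_effect_from_z(
    z_adj: float,
    se: float | None = None,
    mode: str = "se_scale",
    z_raw: float | None = None,
    effect_raw: float | None = None,
) -> float:
    """Convert an adjusted (shrunken) Z-score back to the effect scale.

    ``se_scale``:    ln(OR)* = sigma_hat * X*
    ``ratio_scale``: ln(OR)* = (X*/X) * ln(OR)

    The two agree exactly whenever ln(OR) = sigma_hat * X.
    """
    if mode == "se_scale":
        if se is None or se <= 0:
            raise ValueError("se_scale mode requires a positive standard error")
        return se * z_adj
    if mode == "ratio_scale":
        if z_raw is None or effect_raw is None:
            raise ValueError("ratio_scale mode requires z_raw and effect_raw")
        if z_raw == 0:
            raise ValueError("ratio_scale undefined for z_raw = 0")
        return (z_adj / z_raw) * effect_raw
    raise ConfigurationError(f"unknown mode {mode!r}; use 'se_scale' or 'ratio_scale'")


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_sumstats`."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)
    inconsistent_pz: list = field(default_factory=list)


@dataclass
class ScanStatistics:
    """Per-variant genome-scan summary statistics.

    Holds the vector of normally distributed scan statistics ``X_i ~ N(mu_i, 1)``
    together with their two-sided p-values ``p_i`` and, when available, the
    effect estimates and standard errors they were derived from.  Records are
    sorted by (chrom, pos_bp) and variant IDs are unique.
    """

    table: pd.DataFrame  # columns: snp, chrom, pos, z, p [, beta, se, ...]
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        required = {"snp", "chrom", "pos", "z", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"ScanStatistics table missing columns: {sorted(missing)}")
        if self.table["snp"].duplicated().any():
            dups = self.table.loc[self.table["snp"].duplicated(), "snp"].head(5).tolist()
            raise InputError(f"duplicate variant IDs: {dups}")
        if len(self.table) and (self.table["pos"] < 1).any():
            raise InputError("positions must be >= 1 (1-based base pairs)")
        self.table = self.table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["snp"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos"].to_numpy(dtype=np.int64)


def _sniff_sep(path) -> str:
    """Auto-detect the delimiter among tab, comma and whitespace."""
    if hasattr(path, "read"):
        head = path.read()
        path.seek(0)
        first = head.splitlines()[0] if head else ""
    else:
        with open(path, "rt") as fh:
            first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


_DIRECTION_NEG = re.compile(r"^\s*[-−]")


def _parse_direction(value) -> float:
    """Map a direction token ('+', '-', signed number) to +-1."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return -1.0 if value < 0 else 1.0
    return -1.0 if _DIRECTION_NEG.match(str(value)) else 1.0


def read_sumstats(path, column_map: Mapping[str, str]) -> ScanStatistics:
    """Load a delimited summary-statistics table.

    Parameters
    ----------
    path
        File path (or open text handle) to a delimited table with a header.
        Delimiter is auto-detected among tab, comma and whitespace.
    column_map
        Mapping of logical column names to actual header names.  Required
        logical columns: ``snp``, ``chrom``, ``pos``, plus at least one of the
        statistic combinations {``z``}, {``beta``, ``se``}, {``or``, ``se``},
        {``p``, ``direction``}.

    Rows with unparseable or out-of-domain values (p <= 0, p > 1, se <= 0)
    are dropped and counted in the attached :class:`LoadReport`; rows where
    reported p and z disagree beyond 0.1% relative are flagged in the report
    but kept as-is.
    """
    column_map = {k.lower(): v for k, v in column_map.items()}
    unknown = set(column_map) - set(LOGICAL_COLUMNS)
    if unknown:
        raise ConfigurationError(f"unknown logical columns: {sorted(unknown)}")
    for col in ("snp", "chrom", "pos"):
        if col not in column_map:
            raise ConfigurationError(f"column_map missing required logical column {col!r}")
    has = lambda *cols: all(c in column_map for c in cols)
    if not (has("z") or has("beta", "se") or has("or", "se") or has("p", "direction")):
        raise ConfigurationError(
            "column_map must provide one of: {z}, {beta,se}, {or,se}, {p,direction}"
        )

    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep == r"\s+" else "c")
    missing_actual = [v for v in column_map.values() if v not in df.columns]
    if missing_actual:
        raise ConfigurationError(f"columns not found in file header: {missing_actual}")

    report = LoadReport(n_read=len(df))
    out = pd.DataFrame({
        "snp": df[column_map["snp"]].astype(str),
        "chrom": df[column_map["chrom"]].astype(str),
        "pos": pd.to_numeric(df[column_map["pos"]], errors="coerce"),
    })
    for logical in ("z", "beta", "se", "or", "p"):
        if logical in column_map:
            out[logical] = pd.to_numeric(df[column_map[logical]], errors="coerce")
    if "direction" in column_map:
        out["direction"] = df[column_map["direction"]].map(_parse_direction)

    def drop(frame: pd.DataFrame, mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + n
            frame = frame.loc[~mask]
        return frame

    out = drop(out, out["pos"].isna() | (out["pos"] < 1), "bad position")
    if "p" in out.columns:
        out = drop(out, out["p"].notna() & ((out["p"] <= 0) | (out["p"] > 1)), "p out of (0,1]")
    if "se" in out.columns:
        out = drop(out, out["se"].notna() & (out["se"] <= 0), "se <= 0")
    if "or" in out.columns:
        out = drop(out, out["or"].notna() & (out["or"] <= 0), "OR <= 0")
        out = out.assign(beta=np.log(out["or"].to_numpy(dtype=float)))

    # derive z, preferring reported z, then beta/se, then p + direction
    z = out["z"].to_numpy(dtype=float) if "z" in out.columns else np.full(len(out), np.nan)
    if "beta" in out.columns and "se" in out.columns:
        fill = np.isnan(z) & out["beta"].notna().to_numpy() & out["se"].notna().to_numpy()
        z[fill] = out["beta"].to_numpy(dtype=float)[fill] / out["se"].to_numpy(dtype=float)[fill]
    if "p" in out.columns and "direction" in out.columns:
        pv = out["p"].to_numpy(dtype=float)
        fill = np.isnan(z) & ~np.isnan(pv)
        if fill.any():
            z[fill] = z_from_pvalue_sign(pv[fill], out["direction"].to_numpy(dtype=float)[fill])
    out = out.assign(z=z)
    keep = ~np.isnan(z)
    report.drop_reasons.setdefault("no usable statistic", 0)
    report.drop_reasons["no usable statistic"] += int((~keep).sum())
    out = out.loc[keep]

    # derive p from z where missing; flag (do not fix) reported inconsistencies
    if "p" in out.columns:
        pv = out["p"].to_numpy(dtype=float)
        zz = out["z"].to_numpy(dtype=float)
        have_both = ~np.isnan(pv)
        expected = pvalue_from_z(zz[have_both])
        rel = np.abs(pv[have_both] - expected) / pv[have_both]
        bad = np.flatnonzero(have_both)[rel >= _CONSISTENCY_RTOL]
        report.inconsistent_pz = out["snp"].to_numpy()[bad].tolist()
        pv = np.where(np.isnan(pv), pvalue_from_z(zz), pv)
        out = out.assign(p=pv)
    else:
        out = out.assign(p=pvalue_from_z(out["z"].to_numpy(dtype=float)))

    out = out.drop(columns=[c for c in ("or", "direction") if c in out.columns])
    out["pos"] = out["pos"].astype(np.int64)
    report.n_kept = len(out)
    report.n_dropped = report.n_read - report.n_kept
    report.drop_reasons = {k: v for k, v in report.drop_reasons.items() if v}
    if report.n_kept == 0:
        raise InputError("no usable rows in summary-statistics file")
    return ScanStatistics(out.reset_index(drop=True), report)


def write_adjusted(stats: ScanStatistics, estimates: Sequence, path) -> None:
    """Write the input table plus one column per noncentrality-estimate method.

    ``estimates`` is a sequence of ``NoncentralityEstimates``; each must be
    aligned (same length, same order) to ``stats``.  Output is tab-delimited;
    floats carry 6 significant digits so a round-trip read recovers them.
    """
    out = stats.table.copy()
    for est in estimates:
        values = np.asarray(est.values, dtype=float)
        if len(values) != len(out):
            raise InputError(
                f"estimate vector {est.method!r} has length {len(values)}, expected {len(out)}"
            )
        out[est.method] = values
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
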