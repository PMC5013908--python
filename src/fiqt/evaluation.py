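"""Scoring estimators against simulated ground truth.

Because tail adjustment only corrects statistics above a threshold while the
other estimators correct everything, performance is reported *cumulatively*:
for each grid point t on the -log10 p scale, metrics are computed over the
SNP set S(t) = { i : p_i <= 10^(-t) }, i.e. all statistics at least as
significant as the threshold.  Reported per method and threshold:

- MSE   mean (mu_hat - mu)^2 over S(t)
- R^2   squared Pearson correlation of (mu_hat, mu) over S(t) (NaN when the
        truth or the estimates are constant on S(t), e.g. under the null)
- bias  mean (mu_hat - mu), variance var(mu_hat - mu) (population variance,
        so MSE = bias^2 + variance holds exactly on the same sample)

``compare_methods`` runs replicate simulations, applies every estimator to
each replicate, averages per-threshold metrics across replicates and attaches
Monte-Carlo standard errors.  TA is re-run per threshold, adjusting all
statistics above that threshold, mirroring its cumulative use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import fiqt, fiqt_with_mta, mle_estimate, NoncentralityEstimates
from .empirical_bayes import eb_n, tweedie_estimate
from .simulate import ArmaSpec, SimulationConfig, simulate_scan
from .sumstats import pvalue_from_z, z_from_pvalue_sign
from .tail_adjustment import TaConfig, ta_adjust

__all__ = [
    "EvaluationReport",
    "DEFAULT_THRESHOLDS",
    "cumulative_metrics",
    "compare_methods",
    "make_method",
    "METHOD_CHOICES",
]

DEFAULT_THRESHOLDS = tuple(np.arange(0.0, 8.5, 0.5))

_METRICS = ("mse", "r2", "bias", "variance")


def cumulative_metrics(true_mu, estimates, p, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-threshold cumulative metrics of one estimate vector.

    ``estimates`` may be a :class:`NoncentralityEstimates` or a plain vector.
    Thresholds are -log10 p grid points, ascending.  Rows with empty S(t)
    carry NaN metrics and n_snps = 0.
    """
    values = estimates.values if isinstance(estimates, NoncentralityEstimates) else estimates
    true_mu = np.asarray(true_mu, dtype=float)
    values = np.asarray(values, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (true_mu.shape == values.shape == p.shape):
        raise ValueError(
            f"misaligned vectors: truth {true_mu.shape}, estimates {values.shape}, p {p.shape}"
        )
    ok = ~np.isnan(values) & ~np.isnan(p)
    rows = []
    for t in thresholds:
        sel = ok & (p <= 10.0 ** (-t))
        n = int(sel.sum())
        row = {"threshold": float(t), "n_snps": n}
        if n == 0:
            row.update({m: np.nan for m in _METRICS})
        else:
            err = values[sel] - true_mu[sel]
            row["mse"] = float(np.mean(err**2))
            row["bias"] = float(np.mean(err))
            row["variance"] = float(np.var(err))  # ddof=0: MSE = bias^2 + variance
            if n > 1 and np.var(true_mu[sel]) > 0 and np.var(values[sel]) > 0:
                r = np.corrcoef(values[sel], true_mu[sel])[0, 1]
                row["r2"] = float(r**2)
            else:
                row["r2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["threshold", "n_snps", *_METRICS])


def r2_explained(true_mu, values) -> float:
    """Alternative R^2: 1 - SS_res/SS_tot of the truth (can be negative)."""
    true_mu = np.asarray(true_mu, dtype=float)
    values = np.asarray(values, dtype=float)
    ss_tot = np.sum((true_mu - true_mu.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - np.sum((values - true_mu) ** 2) / ss_tot)


METHOD_CHOICES = ("mle", "fiqt", "eb1", "eb10", "eb50", "eb100", "ta")


def make_method(name: str, **kwargs) -> tuple[str, Callable[[np.ndarray], NoncentralityEstimates]]:
    """Resolve a method name ('mle', 'fiqt', 'eb<N>'/'eb-<N>', 'ta') to a callable.

    Returns (label, fn) with fn mapping a z vector to estimates.  'ta' here is
    the fixed-threshold form (``threshold_c`` kwarg, default the genome-wide
    5e-8 quantile); inside :func:`compare_methods` TA is instead re-run per
    evaluation threshold.
    """
    key = name.lower().replace("-", "").replace("_", "")
    if key == "mle":
        return "MLE", mle_estimate
    if key == "fiqt":
        mta = kwargs.get("mta", "fdr")
        return ("FIQT" if mta == "fdr" else f"FIQT-{mta}"), (
            fiqt if mta == "fdr" else lambda z: fiqt_with_mta(z, mta)
        )
    if key.startswith("eb"):
        n_sets = int(key[2:]) if key[2:] else 1
        n_bins = kwargs.get("n_bins", 120)
        spline_df = kwargs.get("spline_df", 7)
        if n_sets == 1:
            return "EB-1", lambda z: tweedie_estimate(z, n_bins=n_bins, spline_df=spline_df)
        return f"EB-{n_sets}", lambda z: eb_n(z, n_sets, n_bins=n_bins, spline_df=spline_df)
    if key == "ta":
        c = kwargs.get("threshold_c", float(z_from_pvalue_sign(5e-8, 1)))
        return "TA", lambda z: ta_adjust(z, TaConfig(threshold_c=c))
    raise ValueError(f"unknown method {name!r}; choose from {METHOD_CHOICES}")


@dataclass
class EvaluationReport:
    """Replicate-averaged cumulative metrics for a set of estimators.

    ``table`` is long-format: one row per (method, threshold) with the
    replicate means of each metric, their Monte-Carlo standard errors
    (columns ``<metric>_se``) and the mean SNP count per cumulative bin.
    """

    table: pd.DataFrame
    thresholds: tuple
    reps: int
    failures: dict = field(default_factory=dict)

    def metric(self, method: str, name: str) -> np.ndarray:
        sub = self.table[self.table["method"] == method].sort_values("threshold")
        if sub.empty:
            raise KeyError(f"no method {method!r} in report")
        return sub[name].to_numpy()


def _ta_cumulative(z, true_mu, p, thresholds) -> pd.DataFrame:
    """TA scored cumulatively: re-adjust all |z| above each threshold's quantile."""
    rows = []
    for t in thresholds:
        p_thr = 10.0 ** (-t)
        # the full-scan point (p = 1) has selection threshold c = 0: the
        # selection event is certain and TA reduces to the MLE
        if p_thr >= 1.0:
            est = mle_estimate(z)
        else:
            c = float(z_from_pvalue_sign(p_thr, 1))
            est = ta_adjust(z, TaConfig(threshold_c=c))
        rows.append(cumulative_metrics(true_mu, est, p, [t]))
    return pd.concat(rows, ignore_index=True)


def compare_methods(
    config: SimulationConfig,
    methods: Sequence[str] = ("fiqt", "mle"),
    thresholds=DEFAULT_THRESHOLDS,
    spec: ArmaSpec | None = None,
    method_kwargs: dict | None = None,
) -> EvaluationReport:
    """Run replicate simulations and score every estimator on each replicate.

    Deterministic given ``config.seed``: replicate r uses child seeds spawned
    from it.  A method failing on a replicate is recorded in
    ``report.failures`` and that replicate is excluded for that method only.
    """
    if not methods:
        raise ValueError("need at least one method")
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spec = spec or ArmaSpec()
    method_kwargs = method_kwargs or {}
    resolved = []
    for name in methods:
        if name.lower() == "ta":
            resolved.append(("TA", None))  # threshold-dependent, handled separately
        else:
            resolved.append(make_method(name, **method_kwargs.get(name, {})))

    per_method: dict[str, list[pd.DataFrame]] = {label: [] for label, _ in resolved}
    failures: dict[str, list] = {}
    rep_seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    for r in range(config.n_reps):
        scan = simulate_scan(config, spec, seed=rep_seeds[r])
        p = pvalue_from_z(scan.z)
        for label, fn in resolved:
            try:
                if fn is None:
                    per_method[label].append(_ta_cumulative(scan.z, scan.true_mu, p, thresholds))
                else:
                    est = fn(scan.z)
                    per_method[label].append(cumulative_metrics(scan.true_mu, est, p, thresholds))
            except Exception as exc:  # noqa: BLE001 — recorded, replicate dropped for this method
                failures.setdefault(label, []).append((r, repr(exc)))

    frames = []
    for label, tables in per_method.items():
        if not tables:
            continue
        stacked = pd.concat(tables, keys=range(len(tables)), names=["rep"])
        grouped = stacked.groupby("threshold", sort=True)
        mean = grouped[[*_METRICS, "n_snps"]].mean()
        nrep = grouped[list(_METRICS)].count()
        se = grouped[list(_METRICS)].std(ddof=1) / np.sqrt(nrep.clip(lower=1))
        out = mean.reset_index()
        for m in _METRICS:
            out[f"{m}_se"] = se[m].to_numpy()
        out.insert(0, "method", label)
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    return EvaluationReport(
        table=table, thresholds=tuple(thresholds), reps=config.n_reps, failures=failures
    )
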