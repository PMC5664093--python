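"""Per-gene survival screening: median split, Kaplan-Meier, log-rank, BH.

For each gene, the cohort is dichotomized at the median expression
(ties at the median fall to the low half), the two halves are compared by
the standard two-group log-rank test (chi-squared with 1 df), and p-values
are BH-adjusted across the screened gene set; genes with FDR below alpha
are flagged.  A per-gene Cox proportional-hazards regression on continuous
expression is available as an alternative statistic.  Each row also
records which half has the higher estimated survival, so statements like
"patients with lower expression survive longer" can be asserted per gene.

Estimators are delegated to lifelines (KaplanMeierFitter, logrank_test,
CoxPHFitter); this module owns the splitting, screening and FDR logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .pca import bh_adjust

__all__ = [
    "SurvivalCohort",
    "DegenerateSplitError",
    "median_split",
    "km_curve",
    "survival_at",
    "restricted_mean",
    "logrank_test",
    "cox_test",
    "screen_genes",
    "read_survival_table",
]


class DegenerateSplitError(ValueError):
    """Raised when all expression values are identical (no split possible)."""


@dataclass
class SurvivalCohort:
    """Per-patient follow-up time (days, > 0), event flag, and expression.

    ``data`` is indexed by patient id with columns ``time`` (positive),
    ``event`` (1 = death observed, 0 = censored) and ``expression``
    (real-valued expression of a single gene).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time", "event", "expression"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort missing columns: {sorted(missing)}")
        if (self.data["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)


def median_split(c: SurvivalCohort) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Split a cohort at the median expression; ties at the median go low.

    Patients with expression <= median form the low group, the rest the
    high group.  For even cohorts without ties this gives equal halves.
    """
    if len(c) < 4:
        raise ValueError(f"cohort of size {len(c)} too small to split (need >= 4)")
    expr = c.data["expression"]
    med = float(expr.median())
    low = expr <= med
    if low.all() or not low.any():
        raise DegenerateSplitError("all expression values identical; median split undefined")
    return SurvivalCohort(c.data[low]), SurvivalCohort(c.data[~low])


def km_curve(group: SurvivalCohort) -> pd.Series:
    """Kaplan-Meier product-limit survival estimate S(t).

    Returns a step function as a Series indexed by observed times (with
    S(0) = 1 prepended); at each distinct event time with d events among
    n at risk, S multiplies by (1 - d/n).  Censored patients leave the
    risk set after their recorded time.
    """
    if len(group) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(group.data["time"], group.data["event"])
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    return s.rename("S")


def survival_at(curve: pd.Series, t: float) -> float:
    """Evaluate a KM step function at time ``t`` (right-continuous)."""
    s = curve[curve.index <= t]
    return float(s.iloc[-1]) if len(s) else 1.0


def restricted_mean(curve: pd.Series, tau: float) -> float:
    """Area under the KM step function up to ``tau`` (restricted mean)."""
    times = np.asarray(curve.index, dtype=float)
    values = curve.to_numpy(dtype=float)
    if times.size == 0 or times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        values = np.concatenate([[1.0], values])
    keep = times < tau
    t = np.concatenate([times[keep], [tau]])
    v = values[keep]
    # right-continuous step integral: sum of S(t_i) * (t_{i+1} - t_i)
    return float(np.sum(v * np.diff(t)))


def logrank_test(a: SurvivalCohort, b: SurvivalCohort) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-squared statistic, p-value).

    The statistic is the squared sum of observed-minus-expected events in
    group ``a`` over event times, divided by the hypergeometric variance,
    referred to chi-squared with 1 df.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a.data["event"].sum() + b.data["event"].sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    res = _ll_logrank(
        a.data["time"], b.data["time"], a.data["event"], b.data["event"]
    )
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        raise ValueError("log-rank variance is zero; test undefined")
    return stat, float(res.p_value)


def cox_test(c: SurvivalCohort) -> tuple[float, float]:
    """Cox PH regression on continuous expression; returns (Wald z, p)."""
    cph = CoxPHFitter()
    cph.fit(c.data[["time", "event", "expression"]], duration_col="time", event_col="event")
    z = float(cph.summary.loc["expression", "z"])
    return z, float(2 * stats.norm.sf(abs(z)))


def _direction(low: SurvivalCohort, high: SurvivalCohort) -> str:
    """Which half survives longer, by restricted mean up to the common horizon."""
    tau = min(low.data["time"].max(), high.data["time"].max())
    rm_low = restricted_mean(km_curve(low), tau)
    rm_high = restricted_mean(km_curve(high), tau)
    return "low" if rm_low >= rm_high else "high"


def screen_genes(
    cohorts: Mapping[str, SurvivalCohort],
    alpha: float = 0.05,
    method: str = "logrank",
    cancer_label: str = "",
) -> pd.DataFrame:
    """Screen genes for survival association; BH-adjust across the set.

    Returns one row per gene with columns ``gene``, ``cancer``, ``method``,
    ``statistic``, ``pvalue``, ``fdr``, ``n_low``, ``n_high``,
    ``direction`` ("low"/"high" = which half survives better) and
    ``flagged`` (fdr < alpha).  Per-gene failures (degenerate split, zero
    variance) become NA rows rather than aborting the screen.  The BH
    family is the set of genes screened in this call, i.e. one cancer
    label; pool across labels by concatenating cohort maps.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if method not in ("logrank", "cox"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for gene, cohort in cohorts.items():
        row = {
            "gene": gene,
            "cancer": cancer_label,
            "method": method,
            "statistic": np.nan,
            "pvalue": np.nan,
            "n_low": np.nan,
            "n_high": np.nan,
            "direction": pd.NA,
        }
        try:
            low, high = median_split(cohort)
            row["n_low"], row["n_high"] = len(low), len(high)
            row["direction"] = _direction(low, high)
            if method == "logrank":
                row["statistic"], row["pvalue"] = logrank_test(low, high)
            else:
                row["statistic"], row["pvalue"] = cox_test(cohort)
        except (ValueError, DegenerateSplitError):
            pass
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    ok = out["pvalue"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "pvalue"].to_numpy())
    out["flagged"] = out["fdr"] < alpha
    return out


def read_survival_table(path, genes: Optional[list] = None) -> dict:
    """Read survival cohorts from TSV in wide or long layout.

    Wide: columns ``patient_id``, ``time_days``, ``event`` plus one column
    per gene.  Long: columns ``gene``, ``patient_id``, ``time_days``,
    ``event``, ``expression``.  Returns a dict gene -> SurvivalCohort,
    optionally restricted to ``genes``.
    """
    df = pd.read_csv(path, sep="\t")
    base = {"patient_id", "time_days", "event"}
    if not base <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(base)}")
    cohorts: dict = {}
    if "gene" in df.columns and "expression" in df.columns:
        for gene, sub in df.groupby("gene", sort=False):
            sub = sub.set_index("patient_id")
            cohorts[str(gene)] = SurvivalCohort(
                sub.rename(columns={"time_days": "time"})[["time", "event", "expression"]]
            )
    else:
        gene_cols = [c for c in df.columns if c not in base]
        idx = df.set_index("patient_id")
        for gene in gene_cols:
            cohorts[str(gene)] = SurvivalCohort(
                pd.DataFrame(
                    {
                        "time": idx["time_days"],
                        "event": idx["event"],
                        "expression": idx[gene],
                    }
                )
            )
    if genes is not None:
        wanted = set(genes)
        cohorts = {g: c for g, c in cohorts.items() if g in wanted}
    return cohorts
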