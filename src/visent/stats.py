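"""Group statistics: outlier exclusion, Student t-tests, effect sizes,
JZS Bayes factors and brain-behavior regression.

The Bayesian two-sample test uses the default (JZS) prior: a zero-
centered Cauchy distribution on the standardized effect size delta with
scale 0.707.  The Bayes factor in favor of the null is

    BF01 = T_df(t | 0) / integral T_df(t | delta * sqrt(n1 n2/(n1+n2)))
                                  * Cauchy(delta; 0, r) d delta

evaluated by adaptive quadrature over delta, where ``T_df(. | ncp)`` is
the noncentral t density at the observed statistic.  BF01 > 1 favors the
null hypothesis of no group difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = [
    "StatResult",
    "exclude_outliers",
    "student_t",
    "cohen_d_from_t",
    "jzs_bf01",
    "regress",
    "cohort_report",
]

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    """Result of one group contrast or regression."""

    kind: str  # "t_test" or "regression"
    statistic: float  # t or F
    df: tuple  # (df,) for t; (df1, df2) for F
    p: float
    cohen_d: float | None = None
    bf01: float | None = None
    eta2p: float | None = None
    n_per_group: tuple | None = None
    excluded: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "cohen_d": self.cohen_d,
            "bf01": self.bf01,
            "eta2p": self.eta2p,
            "n_per_group": list(self.n_per_group) if self.n_per_group else None,
            "excluded": list(self.excluded),
        }
        return d


def exclude_outliers(
    values: np.ndarray, groups: np.ndarray, k: float = 2.5
) -> np.ndarray:
    """Per-group outlier mask: keep values within k SDs of their group mean.

    Single pass with the sample SD; strict exceedance excludes.  A group
    with zero SD excludes nothing (degenerate case, logged).  Returns a
    boolean inclusion mask.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.ones(values.shape, dtype=bool)
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
        v = values[sel]
        sd = v.std(ddof=1)
        if sd == 0:
            logger.warning("group %r has zero SD; no exclusions", g)
            continue
        keep[sel] = np.abs(v - v.mean()) <= k * sd
    return keep


def student_t(group_a: np.ndarray, group_b: np.ndarray) -> StatResult:
    """Pooled-variance two-sample Student t-test (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(
        kind="t_test",
        statistic=float(t),
        df=(df,),
        p=float(min(p, 1.0)) if p > 0 else float(np.nextafter(0, 1)),
        n_per_group=(n1, n2),
    )


def cohen_d_from_t(t: float, n1: int, n2: int) -> float:
    """Effect size from a two-sample t: d = |t| * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    return float(abs(t) * np.sqrt(1.0 / n1 + 1.0 / n2))


def jzs_bf01(
    t: float, n1: int, n2: int, cauchy_scale: float = 0.707
) -> float:
    """JZS Bayes factor BF01 for a two-sample t statistic.

    Integrates the noncentral-t likelihood over the Cauchy(0, scale)
    effect-size prior by adaptive quadrature and returns the ratio in
    favor of the null.  Raises if the quadrature does not converge.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be positive")
    df = n1 + n2 - 2
    neff = np.sqrt(n1 * n2 / (n1 + n2))

    def integrand(delta):
        return sps.nct.pdf(t, df, delta * neff) * sps.cauchy.pdf(
            delta, 0.0, cauchy_scale
        )

    num, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0 or err > 1e-4 * max(num, 1e-12):
        raise RuntimeError(
            f"quadrature did not converge (value={num}, abserr={err})"
        )
    den = sps.t.pdf(t, df)
    return float(den / num)


def regress(y: np.ndarray, x: np.ndarray) -> StatResult:
    """Simple OLS regression of y on x (with intercept).

    Reports F = (R^2/df1) / ((1-R^2)/df2) with df1 = 1, df2 = n - 2,
    the two-sided p, the slope, and partial eta squared
    ``F*df1 / (F*df1 + df2)``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("regression needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    df1, df2 = 1, n - 2
    if r2 >= 1.0:
        F = np.inf
        p = 0.0
        eta2p = 1.0
    else:
        F = (r2 / df1) / ((1 - r2) / df2)
        p = sps.f.sf(F, df1, df2)
        eta2p = F * df1 / (F * df1 + df2)
    out = StatResult(
        kind="regression",
        statistic=float(F),
        df=(df1, df2),
        p=float(p) if p > 0 else float(np.nextafter(0, 1)),
        eta2p=float(eta2p),
    )
    out.slope = float(res.slope)  # type: ignore[attr-defined]
    out.intercept = float(res.intercept)  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

CONTRAST_METRICS = [
    "rel_amp",
    "abs_amp",
    "itpl",
    "cv",
    "base_full",
    "base_aperiodic",
    "base_periodic",
    "r_squared",
]


def _contrast(df: pd.DataFrame, metric: str, outlier_k: float) -> dict:
    values = df[metric].to_numpy(dtype=float)
    groups = df["group"].to_numpy()
    keep = exclude_outliers(values, groups, k=outlier_k)
    a = values[keep & (groups == "ADS")]
    b = values[keep & (groups == "HC")]
    res = student_t(a, b)
    d = cohen_d_from_t(res.statistic, len(a), len(b))
    bf = jzs_bf01(res.statistic, len(a), len(b))
    excluded = df.loc[~keep, "subject_id"].tolist()
    return {
        "metric": metric,
        "t": res.statistic,
        "df": res.df[0],
        "p": res.p,
        "cohen_d": d,
        "bf01": bf,
        "n_ads": len(a),
        "n_hc": len(b),
        "excluded": ";".join(excluded),
    }


def cohort_report(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    outlier_k: float = 2.5,
    per_freq_prefix: str = "relf_",
) -> dict:
    """Assemble the cohort's full statistics report.

    Parameters
    ----------
    metrics : DataFrame
        One row per subject with columns ``subject_id``, ``group``, the
        contrast metrics (see :data:`CONTRAST_METRICS`; missing columns
        raise) and optionally per-frequency columns named
        ``{per_freq_prefix}{freq}``.
    covariates : DataFrame, optional
        Columns ``subject_id`` and ``score`` (MMSE-like); enables the
        within-ADS regressions of score on absolute and relative
        amplitude.

    Returns
    -------
    dict with keys ``contrasts`` (DataFrame), ``regressions``
    (DataFrame), ``per_freq`` (DataFrame or None).
    """
    required = {"subject_id", "group"} | set(CONTRAST_METRICS)
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")

    contrasts = pd.DataFrame(
        [_contrast(metrics, m, outlier_k) for m in CONTRAST_METRICS]
    )

    reg_rows = []
    if covariates is not None:
        merged = metrics.merge(covariates, on="subject_id")
        ads = merged[merged["group"] == "ADS"]
        for metric in ("abs_amp", "rel_amp"):
            vals = ads[metric].to_numpy(dtype=float)
            keep = exclude_outliers(
                vals, np.repeat("ADS", len(vals)), k=outlier_k
            )
            res = regress(ads["score"].to_numpy(dtype=float)[keep], vals[keep])
            reg_rows.append(
                {
                    "outcome": "score",
                    "predictor": metric,
                    "F": res.statistic,
                    "df1": res.df[0],
                    "df2": res.df[1],
                    "p": res.p,
                    "eta2p": res.eta2p,
                    "slope": res.slope,
                    "n": int(keep.sum()),
                }
            )
    regressions = pd.DataFrame(reg_rows)

    freq_cols = [c for c in metrics.columns if c.startswith(per_freq_prefix)]
    per_freq = None
    if freq_cols:
        rows = []
        for c in freq_cols:
            sub = metrics[["subject_id", "group", c]].dropna()
            try:
                row = _contrast(sub.rename(columns={c: "value"}), "value", outlier_k)
            except ValueError:
                continue
            row["metric"] = c
            row["freq"] = float(c[len(per_freq_prefix):])
            rows.append(row)
        per_freq = pd.DataFrame(rows)

    return {"contrasts": contrasts, "regressions": regressions, "per_freq": per_freq}


def write_report(report: dict, csv_path, json_path) -> None:
    """Write the contrast table as CSV and the full report as JSON."""
    report["contrasts"].to_csv(csv_path, index=False, float_format="%.10g")
    payload = {
        "contrasts": report["contrasts"].to_dict(orient="records"),
        "regressions": report["regressions"].to_dict(orient="records"),
        "per_freq": (
            report["per_freq"].to_dict(orient="records")
            if report["per_freq"] is not None
            else None
        ),
    }
    with open(json_path, "w") as f:
        json.dump(payload, f, indent=1, sort_keys=True)
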