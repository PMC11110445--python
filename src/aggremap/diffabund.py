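"""Empirical-Bayes moderated two-group differential abundance.

Per feature, a pooled-variance two-sample comparison (PFF minus PBS on the
log2 scale) is moderated by shrinking the residual variance s^2 toward a
prior s0^2 estimated across all features.  The prior is a scaled inverse
chi-square with d0 degrees of freedom, fitted in closed form by moment
matching on log variances: the excess variance of log s^2 beyond
trigamma(df/2) determines d0 through trigamma inversion, and the matched
mean determines s0^2.  The moderated statistic

    t = log2FC / sqrt(s2_post * (1/n1 + 1/n2)),
    s2_post = (d0*s0^2 + df*s^2) / (d0 + df)

is referred to a t distribution on df + d0 degrees of freedom (normal in
the d0 -> infinity limit).  With d0 = 0 it reduces exactly to the ordinary
pooled-variance Student t.  P-values are BH-adjusted across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import FeatureTable, SeedList


@dataclass
class VariancePrior:
    """Scaled-inverse-chi-square variance prior: d0 degrees of freedom, scale s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative (possibly inf)")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValueError("s0_sq must be finite and positive")


def group_stats(table: FeatureTable) -> pd.DataFrame:
    """Per-feature group means, log2 fold change and pooled residual variance.

    Requires a complete (post-imputation) matrix and >=2 samples per group.
    log2fc is mean(PFF) - mean(PBS); the pooled variance has
    df = n1 + n2 - 2.
    """
    analytic = table.analytic_samples()
    design = table.design.loc[analytic]
    pff = list(design.index[design["treatment"] == "PFF"])
    pbs = list(design.index[design["treatment"] == "PBS"])
    if len(pff) < 2 or len(pbs) < 2:
        raise ValueError("need at least 2 samples per treatment group")
    values = table.values[analytic]
    if values.isna().any().any():
        raise ValueError("matrix contains missing values; impute before testing")

    x1 = values[pff].to_numpy(dtype=float)
    x2 = values[pbs].to_numpy(dtype=float)
    n1, n2 = len(pff), len(pbs)
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - mean1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return pd.DataFrame(
        {
            "mean_pff": mean1,
            "mean_pbs": mean2,
            "log2fc": mean1 - mean2,
            "s2": s2,
            "df": float(df),
            "n1": n1,
            "n2": n2,
        },
        index=table.meta.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray | pd.Series, df: float) -> VariancePrior:
    """Moment-matching fit of (d0, s0^2) from residual variances.

    Works on log variances: with s^2 ~ s0^2 * chi2_d0(scaled), the variance
    of log s^2 exceeds trigamma(df/2) by trigamma(d0/2); the excess is
    inverted for d0 and the mean is matched for s0^2.  When the empirical
    variance shows no excess, d0 = inf and s0^2 is the mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) < 10:
        raise ValueError("need at least 10 features with positive residual variance")
    z = np.log(pos)
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return VariancePrior(d0=d0, s0_sq=s0_sq)
    return VariancePrior(d0=np.inf, s0_sq=float(pos.mean()))


def moderated_t_test(stats_df: pd.DataFrame, prior: VariancePrior) -> pd.DataFrame:
    """Moderated t, posterior variances and two-sided p-values per feature."""
    d0, s0 = prior.d0, prior.s0_sq
    df = stats_df["df"].to_numpy(dtype=float)
    s2 = stats_df["s2"].to_numpy(dtype=float)
    lfc = stats_df["log2fc"].to_numpy(dtype=float)
    n1 = stats_df["n1"].to_numpy(dtype=float)
    n2 = stats_df["n2"].to_numpy(dtype=float)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    if (se == 0).any():
        warnings.warn("zero posterior variance; infinite t mapped to p=0", RuntimeWarning)

    finite_df = np.where(np.isinf(df_total), 1.0, df_total)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), finite_df),
    )
    p = np.where(np.isinf(t_mod), 0.0, p)

    out = stats_df.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p"] = np.clip(p, 0.0, 1.0)
    return out


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(arr)
    if m == 0:
        return arr.copy()
    order = np.argsort(arr, kind="mergesort")
    scaled = arr[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_test(table: FeatureTable, prior: VariancePrior | None = None) -> pd.DataFrame:
    """Full per-feature moderated test with BH adjustment (no calls yet)."""
    stats_df = group_stats(table)
    if prior is None:
        prior = fit_variance_prior(stats_df["s2"], float(stats_df["df"].iloc[0]))
    res = moderated_t_test(stats_df, prior)
    res["padj"] = bh_adjust(res["p"])
    return res


def call_significant(
    results: pd.DataFrame,
    lfc_cut: float,
    padj_cut: float,
    *,
    ge: bool = False,
    meta: pd.DataFrame | None = None,
    label: str = "seed",
) -> tuple[pd.DataFrame, SeedList, SeedList]:
    """Attach up/down/ns calls and derive protein-level seed lists.

    Strict ``>`` on |log2FC| by default; ``ge=True`` switches to ``>=``
    (the insoluble-fraction convention).  Phosphosite features map to their
    leading protein in the seed lists, keeping a protein if any of its
    sites passes.
    """
    lfc = results["log2fc"]
    padj = results["padj"]
    sig = padj < padj_cut
    if ge:
        up = sig & (lfc >= lfc_cut)
        down = sig & (lfc <= -lfc_cut)
    else:
        up = sig & (lfc > lfc_cut)
        down = sig & (lfc < -lfc_cut)
    out = results.copy()
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))

    def symbols(mask: pd.Series) -> set[str]:
        ids = results.index[mask]
        if meta is not None and "leading_protein" in meta:
            return {str(s).upper() for s in meta.loc[ids, "leading_protein"]}
        return {str(i).upper() for i in ids}

    return (
        out,
        SeedList(f"{label}_up", symbols(up)),
        SeedList(f"{label}_down", symbols(down)),
    )
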