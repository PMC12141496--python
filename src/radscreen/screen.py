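"""Within-donor dose-correlation screen for radioresponsive genes.

For every gene, expression (log2-normalized by default) is correlated
with absorbed dose separately within each donor at a chosen timepoint,
the donor correlations are Fisher z-transformed (variance 1/(n-3)),
and the z values are pooled on the z scale with equal weights:

    z_pooled = mean(z_i)
    W_bar    = mean(1 / (n_i - 3))          within-donor variance
    B        = var(z_i, ddof=1)             between-donor variance

The default is the pure fixed-effects (common-effect) scheme,
T = W_bar / m with a standard-normal reference — the only scheme with
usable power at m = 3 donors, and the one whose confidence intervals
match published within-donor screens of this design.
``include_between=True`` switches to the multiple-imputation-style
(Rubin) combination T = W_bar + (1 + 1/m) * B, referred to a Student t
with Barnard-Rubin adjusted degrees of freedom

    nu = (m - 1) * (1 + W_bar / ((1 + 1/m) * B))**2

when B > 0 (normal when B = 0); it charges donor heterogeneity to the
variance and is extremely conservative at small m.  Either way the
pooled correlation is tanh(z_pooled) with confidence limits
tanh(z_pooled ± q * sqrt(T)).

Genes are then classified as significantly positively / negatively
correlated or nonsignificant, with Benjamini-Hochberg q-values
reported alongside the raw p used for classification by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import filter_low_expression, normalize_log, size_factors_median_of_ratios

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "DonorCorrelation",
    "PooledCorrelation",
    "donor_correlations",
    "pool_rubin",
    "bh_adjust",
    "screen",
]

CLASS_POS = "significant_positive"
CLASS_NEG = "significant_negative"
CLASS_NS = "nonsignificant"
CLASS_UNTESTABLE = "untestable"


def fisher_z(r, clamp_eps: float = 1e-6):
    """Fisher z transform atanh(r), clamping |r| to 1 - clamp_eps.

    Accepts scalars or arrays; |r| > 1 is rejected.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.abs(arr) > 1
    if np.any(bad & ~np.isnan(arr)):
        raise ValueError("correlation outside [-1, 1]")
    clipped = np.sign(arr) * np.minimum(np.abs(arr), 1.0 - clamp_eps)
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z):
    """tanh(z); inverse of :func:`fisher_z` up to the clamp."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


@dataclass
class DonorCorrelation:
    """One donor's expression-vs-dose Pearson correlation."""

    donor_id: str
    r: float
    n: int  # number of (dose, expression) pairs
    z: float  # Fisher z of r
    var: float  # 1 / (n - 3)


@dataclass
class PooledCorrelation:
    """Fixed-effects pooled correlation with Rubin-style variance."""

    m: int
    z_pooled: float
    w_bar: float
    b: float
    t_var: float
    df: float  # inf means a normal reference
    r_pooled: float
    ci_low: float
    ci_high: float
    p: float


def donor_correlations(
    expr: pd.Series,
    design: pd.DataFrame,
    time_h: float,
    clamp_eps: float = 1e-6,
) -> list[DonorCorrelation]:
    """Per-donor Pearson correlation of one gene's expression with dose.

    ``expr`` is indexed by sample id.  Only samples at ``time_h`` are
    used; every donor needs >= 4 distinct doses there (so the Fisher
    variance 1/(n-3) is defined).  Donors with constant expression are
    dropped with a warning; the caller decides what to do when fewer
    than two donors remain.
    """
    sub = design[design["time_h"] == time_h]
    if sub.empty:
        raise ValueError(f"no samples at time {time_h} h")
    out: list[DonorCorrelation] = []
    for donor_id, grp in sub.groupby("donor_id", sort=True):
        doses = grp["dose_gy"].to_numpy(dtype=float)
        if len(np.unique(doses)) < 4:
            raise ValueError(
                f"donor {donor_id}: needs >= 4 distinct doses at {time_h} h, "
                f"has {len(np.unique(doses))}"
            )
        y = expr.reindex(grp["sample_id"]).to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"donor {donor_id}: expression missing for some samples")
        # relative tolerance: normalization leaves ~1e-16 jitter on
        # genuinely constant rows
        if y.max() - y.min() <= 1e-12 * max(1.0, np.abs(y).max()):
            warnings.warn(
                f"donor {donor_id}: constant expression, correlation undefined; "
                "donor dropped",
                stacklevel=2,
            )
            continue
        r = float(np.corrcoef(doses, y)[0, 1])
        n = len(doses)
        out.append(
            DonorCorrelation(
                donor_id=donor_id,
                r=r,
                n=n,
                z=fisher_z(r, clamp_eps),
                var=1.0 / (n - 3),
            )
        )
    return out


def pool_rubin(
    donor_corrs: list[DonorCorrelation],
    conf: float = 0.95,
    include_between: bool = False,
) -> PooledCorrelation:
    """Pool donor correlations on the Fisher z scale.

    See the module docstring for the formulas.  With a single donor the
    between-donor variance is undefined and set to 0 with a warning.
    """
    m = len(donor_corrs)
    if m == 0:
        raise ValueError("no donor correlations to pool")
    z = np.array([d.z for d in donor_corrs])
    var = np.array([d.var for d in donor_corrs])
    z_pooled = float(np.mean(z))
    w_bar = float(np.mean(var))
    if m == 1:
        warnings.warn("single donor: between-donor variance set to 0", stacklevel=2)
        b = 0.0
    else:
        b = float(np.var(z, ddof=1))
    if include_between:
        t_var = w_bar + (1.0 + 1.0 / m) * b
    else:
        t_var = w_bar / m
    if include_between and b > 0.0:
        df = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = math.inf
    se = math.sqrt(t_var)
    stat = z_pooled / se
    if math.isinf(df):
        p = 2.0 * stats.norm.sf(abs(stat))
        q = stats.norm.ppf(0.5 + conf / 2.0)
    else:
        p = 2.0 * stats.t.sf(abs(stat), df)
        q = stats.t.ppf(0.5 + conf / 2.0, df)
    return PooledCorrelation(
        m=m,
        z_pooled=z_pooled,
        w_bar=w_bar,
        b=b,
        t_var=t_var,
        df=df,
        r_pooled=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(z_pooled - q * se)),
        ci_high=float(np.tanh(z_pooled + q * se)),
        p=float(min(p, 1.0)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} NaN p-value(s) excluded from BH adjustment", stacklevel=2)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def screen(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    time_h: float,
    *,
    alpha: float = 0.05,
    classify_on: str = "p",  # or "q"
    conf: float = 0.95,
    include_between: bool = False,
    min_mean: float = 10.0,
    pseudocount: float = 1.0,
    log_scale: bool = True,
    clamp_eps: float = 1e-6,
) -> pd.DataFrame:
    """Run the full per-gene dose-correlation screen at one timepoint.

    Pipeline: expression filter -> median-of-ratios size factors ->
    log2 normalization (or raw normalized counts with
    ``log_scale=False``) -> per-donor Pearson r vs dose ->
    Fisher-z/Rubin pooling -> BH across tested genes -> sign
    classification at ``alpha`` on raw p (default) or q.

    Returns a DataFrame indexed by gene, sorted by |r_pooled|
    descending (ties by p, then gene id), with per-donor correlations,
    all pooling intermediates, p, q, and class.  Genes with fewer than
    two usable donors are flagged ``untestable`` rather than aborting
    the screen.
    """
    if classify_on not in ("p", "q"):
        raise ValueError("classify_on must be 'p' or 'q'")
    kept = filter_low_expression(counts, min_mean=min_mean)
    if kept.empty:
        raise ValueError("no genes pass the expression filter")
    sf = size_factors_median_of_ratios(kept)
    if log_scale:
        expr = normalize_log(kept, sf, pseudocount=pseudocount)
    else:
        expr = kept.div(sf, axis=1)

    sub = design[design["time_h"] == time_h]
    if sub.empty:
        raise ValueError(f"no samples at time {time_h} h")
    donors = sorted(sub["donor_id"].unique())
    if len(donors) < 2:
        raise ValueError("screen needs >= 2 donors")

    genes = expr.index
    n_genes = len(genes)
    m_all = len(donors)
    r_mat = np.full((n_genes, m_all), np.nan)
    n_vec = np.zeros(m_all, dtype=int)
    for j, donor in enumerate(donors):
        grp = sub[sub["donor_id"] == donor]
        doses = grp["dose_gy"].to_numpy(dtype=float)
        if len(np.unique(doses)) < 4:
            raise ValueError(
                f"donor {donor}: needs >= 4 distinct doses at {time_h} h"
            )
        n_vec[j] = len(doses)
        y = expr[grp["sample_id"]].to_numpy(dtype=float)
        xc = doses - doses.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        sy = np.sqrt((yc**2).sum(axis=1))
        sx = math.sqrt((xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (yc @ xc) / (sy * sx)
        # constant expression (up to normalization float jitter): donor
        # dropped for that gene
        spread = y.max(axis=1) - y.min(axis=1)
        const = spread <= 1e-12 * np.maximum(1.0, np.abs(y).max(axis=1))
        r[const | (sy == 0)] = np.nan
        r_mat[:, j] = r

    z = np.where(np.isnan(r_mat), np.nan, fisher_z(np.nan_to_num(r_mat), clamp_eps))
    var_i = 1.0 / (n_vec - 3).astype(float)
    used = ~np.isnan(z)
    m_used = used.sum(axis=1)
    testable = m_used >= 2
    n_dropped = int((~testable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} gene(s) untestable (fewer than 2 usable donors)",
            stacklevel=2,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z_pooled = np.nanmean(z, axis=1)
        w_bar = np.nanmean(np.where(used, var_i[None, :], np.nan), axis=1)
        b = np.nanvar(z, axis=1, ddof=1)
    if include_between:
        t_var = w_bar + (1.0 + 1.0 / m_used) * b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (m_used - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m_used) * b)) ** 2
        df = np.where(b > 0, df, np.inf)
    else:
        t_var = w_bar / m_used
        df = np.full(n_genes, np.inf)
    se = np.sqrt(t_var)
    stat = z_pooled / se
    finite_df = np.isfinite(df)
    p = np.empty(n_genes)
    qcrit = np.empty(n_genes)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(stat[finite_df]), df[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(stat[~finite_df]))
    np.minimum(p, 1.0, out=p)
    qcrit[finite_df] = stats.t.ppf(0.5 + conf / 2.0, df[finite_df])
    qcrit[~finite_df] = stats.norm.ppf(0.5 + conf / 2.0)

    for arr in (z_pooled, w_bar, b, t_var, p):
        arr[~testable] = np.nan

    q = bh_adjust(np.where(testable, p, np.nan))
    crit = p if classify_on == "p" else q
    r_pooled = np.tanh(z_pooled)
    cls = np.where(
        ~testable,
        CLASS_UNTESTABLE,
        np.where(
            (crit < alpha) & (r_pooled > 0),
            CLASS_POS,
            np.where((crit < alpha) & (r_pooled < 0), CLASS_NEG, CLASS_NS),
        ),
    )

    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for j, donor in enumerate(donors):
        table[f"r_{donor}"] = r_mat[:, j]
    table["n_donors_used"] = m_used
    table["z_pooled"] = z_pooled
    table["w_bar"] = w_bar
    table["b"] = b
    table["t_var"] = t_var
    table["df"] = df
    table["r_pooled"] = r_pooled
    table["ci_low"] = np.tanh(z_pooled - qcrit * se)
    table["ci_high"] = np.tanh(z_pooled + qcrit * se)
    table["p"] = p
    table["q"] = q
    table["class"] = cls
    table = table.sort_values(
        by=["r_pooled", "p", "gene"],
        key=lambda s: -s.abs() if s.name == "r_pooled" else s,
        kind="mergesort",
    )
    return table
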