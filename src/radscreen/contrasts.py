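"""Paired dose-vs-sham and time-effect contrasts.

A deliberately simple differential-expression stage: per-donor log2
fold changes between two conditions of the factorial design, tested
with a one-sample t across donors (optionally with empirical-Bayes
style variance moderation toward the across-gene mean variance).  It
feeds DEG lists to enrichment and readout vectors to TF-activity
inference; it does not model count dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust

__all__ = ["ContrastSpec", "paired_lfc", "paired_test", "interaction_contrast"]


@dataclass(frozen=True)
class ContrastSpec:
    """Numerator and denominator (dose_gy, time_h) conditions, paired by donor."""

    num: tuple[float, float]  # (dose_gy, time_h)
    den: tuple[float, float]

    def __post_init__(self) -> None:
        if self.num == self.den:
            raise ValueError("numerator and denominator conditions are identical")


def _condition_samples(design: pd.DataFrame, cond: tuple[float, float]) -> pd.Series:
    dose, time = cond
    sub = design[(design["dose_gy"] == dose) & (design["time_h"] == time)]
    dup = sub["donor_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"condition {cond}: multiple samples for donor(s) "
            f"{sorted(sub.loc[dup, 'donor_id'])}"
        )
    return sub.set_index("donor_id")["sample_id"]


def paired_lfc(
    expr: pd.DataFrame, design: pd.DataFrame, spec: ContrastSpec
) -> pd.DataFrame:
    """Per-gene, per-donor log2 fold change numerator - denominator.

    ``expr`` must already be on the log2 scale.  Donors missing either
    condition are excluded with a warning.
    """
    num = _condition_samples(design, spec.num)
    den = _condition_samples(design, spec.den)
    donors = sorted(set(num.index) & set(den.index))
    missing = sorted(set(num.index) ^ set(den.index))
    if missing:
        warnings.warn(
            f"donor(s) {missing} missing one condition; excluded", stacklevel=2
        )
    if not donors:
        raise ValueError("no donor has both contrast conditions")
    lfc = pd.DataFrame(index=expr.index.copy())
    for d in donors:
        lfc[d] = expr[num[d]] - expr[den[d]]
    return lfc


def paired_test(
    lfcs: pd.DataFrame,
    moderation: str = "none",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """One-sample t of per-donor log2 fold changes against 0.

    ``moderation="shrink"`` replaces each gene's variance s2_g by
    (prior_df * s2_bar + df * s2_g) / (prior_df + df), where s2_bar is
    the across-gene mean variance, and adds prior_df to the degrees of
    freedom — stabilizing tiny-m designs.  With ``moderation="none"`` a
    gene with zero variance and nonzero mean falls back to the
    moderated variance alone (a zero-variance, zero-mean gene gets
    t = 0, p = 1).

    Returns per gene: each donor's LFC, mean, t, df, p, BH q, and
    direction ("up"/"down"/"none" by the sign of the mean LFC).
    """
    if moderation not in ("none", "shrink"):
        raise ValueError("moderation must be 'none' or 'shrink'")
    m = lfcs.shape[1]
    if m < 2:
        raise ValueError("paired test needs >= 2 donors")
    x = lfcs.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    df0 = float(m - 1)
    s2_bar = float(s2.mean())

    if moderation == "shrink":
        s2_used = (prior_df * s2_bar + df0 * s2) / (prior_df + df0)
        df_used = np.full_like(s2, df0 + prior_df)
    else:
        s2_used = s2.copy()
        df_used = np.full_like(s2, df0)
        degenerate = (s2 == 0) & (mean != 0)
        if degenerate.any():
            s2_used[degenerate] = s2_bar
            df_used[degenerate] = prior_df

    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    ok = s2_used > 0
    t[ok] = mean[ok] / np.sqrt(s2_used[ok] / m)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_used[ok])
    # zero variance everywhere but a nonzero mean: report an exact effect
    hard = ~ok & (mean != 0)
    t[hard] = np.sign(mean[hard]) * np.inf
    p[hard] = 0.0
    p[~ok & (mean == 0)] = 1.0
    np.minimum(p, 1.0, out=p)
    # keep p strictly positive so BH is defined even for underflows
    np.maximum(p, np.finfo(float).tiny, out=p)

    out = lfcs.copy()
    out.columns = [f"lfc_{c}" for c in lfcs.columns]
    out["lfc"] = mean
    out["t"] = t
    out["df"] = df_used
    out["p"] = p
    out["q"] = bh_adjust(p)
    out["direction"] = np.where(mean > 0, "up", np.where(mean < 0, "down", "none"))
    return out


def interaction_contrast(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    dose_gy: float,
    times: tuple[float, float] = (2.0, 6.0),
    sham_gy: float = 0.0,
    moderation: str = "none",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Dose x time interaction: late dose effect minus early dose effect.

    Per donor: [expr(dose, late) - expr(sham, late)] -
    [expr(dose, early) - expr(sham, early)], then :func:`paired_test`.
    """
    early, late = times
    lfc_late = paired_lfc(expr, design, ContrastSpec((dose_gy, late), (sham_gy, late)))
    lfc_early = paired_lfc(expr, design, ContrastSpec((dose_gy, early), (sham_gy, early)))
    donors = sorted(set(lfc_late.columns) & set(lfc_early.columns))
    if not donors:
        raise ValueError("no donor has all four interaction conditions")
    diff = lfc_late[donors] - lfc_early[donors]
    return paired_test(diff, moderation=moderation, prior_df=prior_df)
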