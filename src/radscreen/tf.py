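"""Transcription-factor activity by univariate linear model (ULM).

For each TF, a regressor x is laid over *all* genes of the readout
vector: x_g is the signed regulon weight if g is a target of the TF
and 0 otherwise.  The readout y (typically contrast t-statistics, or
log2 fold changes) is regressed on x by ordinary least squares with an
intercept, and the slope's t-value is the inferred activity — positive
activity means targets with positive weights move up.  This is
equivalent to t = r * sqrt(n - 2) / sqrt(1 - r**2) for the Pearson
correlation r between x and y, which makes the score invariant to
scaling or shifting of the readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust

__all__ = ["read_network", "validate_network", "ulm_activity", "activity_matrix", "TFActivityMatrix"]

#: activity assigned when the regression has zero residual variance
ACTIVITY_CAP = 1e6


def validate_network(network: pd.DataFrame) -> pd.DataFrame:
    """Check a TF->target edge table (columns source, target, weight)."""
    required = ["source", "target", "weight"]
    missing = [c for c in required if c not in network.columns]
    if missing:
        raise ValueError(f"network is missing column(s): {missing}")
    net = network[required].copy()
    net["weight"] = pd.to_numeric(net["weight"], errors="raise")
    if not np.isfinite(net["weight"]).all():
        raise ValueError("network weights must be finite")
    if (net["weight"] == 0).any():
        bad = net.loc[net["weight"] == 0, ["source", "target"]].to_records(index=False)
        raise ValueError(f"zero-weight edge(s) not allowed: {list(bad)[:5]}")
    dup = net.duplicated(subset=["source", "target"])
    if dup.any():
        offenders = net.loc[dup, ["source", "target"]].to_records(index=False)
        raise ValueError(f"duplicate (source, target) edge(s): {list(offenders)[:5]}")
    return net


def read_network(path) -> pd.DataFrame:
    """Read and validate a tab-separated regulon network."""
    net = pd.read_csv(path, sep="\t", comment="#")
    return validate_network(net)


def ulm_activity(
    readout: pd.Series,
    network: pd.DataFrame,
    min_targets: int = 5,
) -> pd.DataFrame:
    """Score every TF in ``network`` against one readout vector.

    Parameters
    ----------
    readout
        Per-gene statistic indexed by gene id (e.g. contrast t-values).
    network
        Validated edge table (see :func:`validate_network`).
    min_targets
        TFs with fewer regulon targets among the readout genes are
        excluded; their ids are listed in ``result.attrs["excluded"]``
        and in a warning.

    Returns
    -------
    pandas.DataFrame
        Indexed by TF: ``n_targets, slope, activity`` (slope t-value),
        ``p`` (two-sided, df = n_genes - 2), ``q`` (BH across TFs), and
        ``capped`` flagging zero-residual-variance degeneracies.
    """
    net = validate_network(network)
    y = readout.astype(float)
    if y.isna().any():
        raise ValueError("readout contains NaN")
    genes = y.index
    n = len(genes)
    if n < 3:
        raise ValueError("readout must cover >= 3 genes")
    yv = y.to_numpy()
    yc = yv - yv.mean()
    syy = float(yc @ yc)

    gene_pos = pd.Series(np.arange(n), index=genes)
    rows = []
    excluded = []
    for tf, edges in net.groupby("source", sort=True):
        hit = edges["target"].isin(genes)
        k = int(hit.sum())
        if k < min_targets:
            excluded.append(tf)
            continue
        idx = gene_pos[edges.loc[hit, "target"]].to_numpy()
        w = edges.loc[hit, "weight"].to_numpy(dtype=float)
        x = np.zeros(n)
        x[idx] = w
        xc = x - x.mean()
        sxx = float(xc @ xc)
        sxy = float(xc @ yv)
        slope = sxy / sxx
        # residual SS of y on x with intercept
        ss_res = syy - sxy**2 / sxx
        capped = False
        if syy == 0.0:
            tval, p = 0.0, 1.0
        elif ss_res <= 0.0:
            tval = float(np.sign(slope)) * ACTIVITY_CAP
            p = 0.0
            capped = True
        else:
            se = np.sqrt(ss_res / (n - 2) / sxx)
            tval = slope / se
            p = 2.0 * stats.t.sf(abs(tval), n - 2)
        rows.append(
            {
                "tf": tf,
                "n_targets": k,
                "slope": slope,
                "activity": tval,
                "p": min(p, 1.0),
                "capped": capped,
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} TF(s) below min_targets={min_targets}: "
            f"{excluded[:10]}{'...' if len(excluded) > 10 else ''}",
            stacklevel=2,
        )
    result = pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame(
        columns=["n_targets", "slope", "activity", "p", "capped"]
    )
    if len(result):
        result["q"] = bh_adjust(np.maximum(result["p"].to_numpy(), 1e-300))
    result.attrs["excluded"] = excluded
    return result


@dataclass
class TFActivityMatrix:
    """TF x condition activity scores with per-condition p and q."""

    activity: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    def top_variable(self, k: int = 25) -> list[str]:
        """TF ids of the k most variable rows across conditions."""
        if k > len(self.activity):
            warnings.warn(
                f"k={k} exceeds the {len(self.activity)} scored TFs; returning all",
                stacklevel=2,
            )
            k = len(self.activity)
        order = self.activity.var(axis=1, ddof=1 if self.activity.shape[1] > 1 else 0)
        return order.sort_values(ascending=False, kind="mergesort").head(k).index.tolist()


def activity_matrix(
    readouts: pd.DataFrame,
    network: pd.DataFrame,
    min_targets: int = 5,
) -> TFActivityMatrix:
    """Apply :func:`ulm_activity` to every column of ``readouts``.

    Only TFs scored in every condition are kept in the matrix.
    """
    if readouts.shape[1] < 1:
        raise ValueError("need at least one readout column")
    acts, ps = {}, {}
    for col in readouts.columns:
        res = ulm_activity(readouts[col], network, min_targets=min_targets)
        acts[col] = res["activity"]
        ps[col] = res["p"]
    act = pd.DataFrame(acts).dropna()
    p = pd.DataFrame(ps).loc[act.index]
    q = p.apply(lambda c: pd.Series(bh_adjust(c.to_numpy()), index=c.index))
    return TFActivityMatrix(activity=act, p=p, q=q)
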