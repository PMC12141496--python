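"""Synthetic whole-blood irradiation RNA-seq counts.

Generates gene-by-sample negative-binomial count matrices emulating an
ex vivo blood irradiation experiment: a small number of donors, graded
X-ray doses including a sham (0 Gy) control, and two incubation
timepoints.  The dominant sources of variation are donor identity and
time in culture, with a minority of genes responding to dose — the
structure a dose-correlation screen has to recover.

The per-sample log2 mean of gene ``g`` in sample ``s`` is

    eta_gs = beta0_g + u_{g,d(s)} + sex_g * 1[donor female]
             + gamma_g * 1[t_s late] + delta_g * f(dose_s)
             + phi_g * f(dose_s) * 1[t_s late]

and counts are drawn NB(mean = L_s * 2**eta_gs, dispersion alpha_g)
with variance mu + alpha * mu**2.  Every nonzero effect is recorded in
a ground-truth table so recovery can be scored exactly.

Randomness is split per gene from the master seed, so simulating a
subset of genes reproduces exactly the same rows as the full run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "generate_design",
    "default_design",
    "simulate_counts",
    "spike_tf_activity",
    "DEFAULT_DONORS",
    "DEFAULT_DOSES_GY",
    "DEFAULT_TIMES_H",
]

SEXES = ("male", "female")

#: Study-design defaults: three donors (two male, one female),
#: five doses including sham, two incubation timepoints.
DEFAULT_DONORS: tuple[tuple[str, str], ...] = (
    ("D1", "male"),
    ("D2", "male"),
    ("D3", "female"),
)
DEFAULT_DOSES_GY: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
DEFAULT_TIMES_H: tuple[float, ...] = (2.0, 6.0)

# Counts above this cannot be represented exactly as floats; the NB
# mean is rejected before drawing.
_MAX_SAFE_MEAN = float(2**53)


def generate_design(
    donors: Sequence[tuple[str, str]] = DEFAULT_DONORS,
    doses_gy: Sequence[float] = DEFAULT_DOSES_GY,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
) -> pd.DataFrame:
    """Build a full-factorial donor x time x dose sample sheet.

    Parameters
    ----------
    donors
        Sequence of ``(donor_id, sex)`` pairs; sex is "male" or "female".
    doses_gy
        Distinct non-negative doses in Gy; must include 0 (sham) and at
        least one nonzero dose.
    times_h
        Distinct positive incubation times in hours.

    Returns
    -------
    pandas.DataFrame
        One row per sample with columns ``sample_id, donor_id, sex,
        dose_gy, time_h``, ordered by donor, then time, then dose.
    """
    donors = list(donors)
    if len(donors) < 1:
        raise ValueError("need at least one donor")
    ids = [d for d, _ in donors]
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise ValueError(f"duplicate donor ids: {dupes}")
    for d, sex in donors:
        if sex not in SEXES:
            raise ValueError(f"donor {d!r}: sex must be one of {SEXES}, got {sex!r}")
    doses = sorted(set(float(x) for x in doses_gy))
    if any(x < 0 for x in doses):
        raise ValueError("doses must be non-negative")
    if len(doses) < 2 or 0.0 not in doses:
        raise ValueError("need >=2 distinct doses including 0 Gy (sham)")
    times = sorted(set(float(t) for t in times_h))
    if len(times) < 1 or any(t <= 0 for t in times):
        raise ValueError("need >=1 positive timepoint")

    rows = []
    for donor_id, sex in donors:
        for t in times:
            for dose in doses:
                rows.append(
                    {
                        "sample_id": f"{donor_id}_{t:g}h_{dose:g}Gy",
                        "donor_id": donor_id,
                        "sex": sex,
                        "dose_gy": dose,
                        "time_h": t,
                    }
                )
    return pd.DataFrame(rows)


def default_design() -> pd.DataFrame:
    """The 3 donor x 5 dose x 2 time (30 sample) default design."""
    return generate_design()


@dataclass
class SimParams:
    """Generator settings.

    Effect sizes are on the log2 scale.  ``slope_*`` describes the
    per-Gy dose slope delta_g of dose-responsive genes (magnitude drawn
    normal, sign positive with probability ``slope_pos_frac``);
    ``time_effect_*`` likewise for the time-in-culture effect gamma_g.
    ``interaction_scale`` sets phi_g = interaction_scale * delta_g so
    the dose response is stronger at the late timepoint.  Dispersion
    alpha_g is lognormal with the given median; alpha == 0 means
    noise-free rounded means (a deterministic limit used in contract
    tests).
    """

    n_genes: int = 2000
    donors: Sequence[tuple[str, str]] = DEFAULT_DONORS
    doses_gy: Sequence[float] = DEFAULT_DOSES_GY
    times_h: Sequence[float] = DEFAULT_TIMES_H
    frac_dose_responsive: float = 0.05
    frac_time_responsive: float = 0.30
    slope_mean: float = 0.7
    slope_sd: float = 0.2
    slope_pos_frac: float = 0.6
    interaction_scale: float = 0.5
    time_effect_mean: float = 1.3
    time_effect_sd: float = 0.4
    time_pos_frac: float = 0.5
    donor_sd: float = 0.4
    sex_effect_sd: float = 0.9
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion_median: float = 0.05
    dispersion_log_sd: float = 0.5
    libsize_log_sd: float = 0.2
    dose_transform: str = "identity"  # or "log1p"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in (
            "slope_sd",
            "time_effect_sd",
            "donor_sd",
            "sex_effect_sd",
            "baseline_log2_sd",
            "dispersion_log_sd",
            "libsize_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "frac_dose_responsive",
            "frac_time_responsive",
            "slope_pos_frac",
            "time_pos_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion_median < 0:
            raise ValueError("dispersion_median must be >= 0")
        if self.dose_transform not in ("identity", "log1p"):
            raise ValueError("dose_transform must be 'identity' or 'log1p'")


def _dose_fn(params: SimParams) -> Callable[[np.ndarray], np.ndarray]:
    if params.dose_transform == "log1p":
        return np.log1p
    return lambda x: x


def _gene_seedseq(seed: int, gene_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(int(seed), 0), spawn_key=(gene_index,))


def _libsize_factors(seed: int, n_samples: int, log_sd: float) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 1)))
    ls = np.exp(rng.normal(0.0, log_sd, size=n_samples))
    # divide out geometric mean so size factors are identifiable
    return ls / np.exp(np.mean(np.log(ls)))


def _draw_gene_params(rng: np.random.Generator, params: SimParams, n_donors: int) -> dict:
    beta0 = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd)
    if params.dispersion_median == 0:
        alpha = 0.0
    else:
        alpha = float(
            np.exp(rng.normal(math.log(params.dispersion_median), params.dispersion_log_sd))
        )
    u = rng.normal(0.0, params.donor_sd, size=n_donors)
    sex_off = rng.normal(0.0, params.sex_effect_sd)
    is_dose = bool(rng.uniform() < params.frac_dose_responsive)
    sign_d = 1.0 if rng.uniform() < params.slope_pos_frac else -1.0
    delta = sign_d * abs(rng.normal(params.slope_mean, params.slope_sd)) if is_dose else 0.0
    phi = params.interaction_scale * delta
    is_time = bool(rng.uniform() < params.frac_time_responsive)
    sign_t = 1.0 if rng.uniform() < params.time_pos_frac else -1.0
    gamma = (
        sign_t * abs(rng.normal(params.time_effect_mean, params.time_effect_sd))
        if is_time
        else 0.0
    )
    return {
        "baseline_log2": beta0,
        "dispersion": alpha,
        "donor_offsets": u,
        "sex_offset": sex_off,
        "is_dose_responsive": is_dose,
        "slope": delta,
        "interaction": phi,
        "is_time_responsive": is_time,
        "time_effect": gamma,
    }


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _build_eta(
    design: pd.DataFrame, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 means plus the ground-truth effect table."""
    donor_ids = [d for d, _ in params.donors]
    donor_idx = design["donor_id"].map({d: i for i, d in enumerate(donor_ids)})
    if donor_idx.isna().any():
        unknown = sorted(set(design.loc[donor_idx.isna(), "donor_id"]))
        raise ValueError(f"design contains donors absent from params.donors: {unknown}")
    donor_idx = donor_idx.to_numpy(dtype=int)
    female = (design["sex"] == "female").to_numpy(dtype=float)
    t_late = (design["time_h"] > design["time_h"].min()).to_numpy(dtype=float)
    fdose = _dose_fn(params)(design["dose_gy"].to_numpy(dtype=float))

    genes = _gene_ids(params.n_genes)
    eta = np.empty((params.n_genes, len(design)))
    records = []
    for g in range(params.n_genes):
        prng = np.random.default_rng(_gene_seedseq(params.seed, g).spawn(2)[0])
        gp = _draw_gene_params(prng, params, len(donor_ids))
        eta[g] = (
            gp["baseline_log2"]
            + gp["donor_offsets"][donor_idx]
            + gp["sex_offset"] * female
            + gp["time_effect"] * t_late
            + gp["slope"] * fdose
            + gp["interaction"] * fdose * t_late
        )
        rec = {
            "gene": genes[g],
            "baseline_log2": gp["baseline_log2"],
            "dispersion": gp["dispersion"],
            "is_dose_responsive": gp["is_dose_responsive"],
            "slope": gp["slope"],
            "interaction": gp["interaction"],
            "is_time_responsive": gp["is_time_responsive"],
            "time_effect": gp["time_effect"],
            "sex_offset": gp["sex_offset"],
        }
        for i, d in enumerate(donor_ids):
            rec[f"u_{d}"] = gp["donor_offsets"][i]
        records.append(rec)
    eta_df = pd.DataFrame(eta, index=pd.Index(genes, name="gene"), columns=design["sample_id"])
    truth = pd.DataFrame(records).set_index("gene")
    return eta_df, truth


def simulate_counts(
    design: pd.DataFrame,
    params: SimParams,
    eta_modifier: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a count matrix for ``design`` under ``params``.

    Parameters
    ----------
    design
        Sample sheet from :func:`generate_design`.
    params
        Generator settings; ``params.donors`` must cover every donor in
        the design.
    eta_modifier
        Optional hook applied to the gene x sample log2-mean matrix
        before counts are drawn (used e.g. to spike transcription-factor
        activity via :func:`spike_tf_activity`).

    Returns
    -------
    (counts, truth)
        ``counts``: integer DataFrame, genes x samples.  ``truth``: one
        row per gene with every simulated effect, plus library sizes in
        ``truth.attrs["libsize"]``.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    eta, truth = _build_eta(design, params)
    if eta_modifier is not None:
        eta = eta_modifier(eta)
        if not eta.index.equals(truth.index) or list(eta.columns) != list(
            design["sample_id"]
        ):
            raise ValueError("eta_modifier must preserve gene and sample labels")

    libsize = _libsize_factors(params.seed, len(design), params.libsize_log_sd)
    counts = np.empty(eta.shape, dtype=np.int64)
    eta_arr = eta.to_numpy()
    alphas = truth["dispersion"].to_numpy()
    for g in range(len(truth)):
        mu = libsize * np.exp2(eta_arr[g])
        if np.max(mu) > _MAX_SAFE_MEAN:
            raise OverflowError(
                f"gene {truth.index[g]}: NB mean {np.max(mu):.3g} exceeds the "
                "integer-safe range; lower baseline_log2 or effect sizes"
            )
        if alphas[g] == 0.0:
            counts[g] = np.rint(mu).astype(np.int64)
        else:
            crng = np.random.default_rng(_gene_seedseq(params.seed, g).spawn(2)[1])
            lam = crng.gamma(shape=1.0 / alphas[g], scale=alphas[g] * mu)
            counts[g] = crng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=eta.index.copy(), columns=eta.columns.copy())
    truth.attrs["libsize"] = pd.Series(libsize, index=eta.columns.copy())
    return counts_df, truth


def spike_tf_activity(
    eta: pd.DataFrame,
    network: pd.DataFrame,
    tf_shifts: Mapping[str, float],
    samples: Iterable[str] | None = None,
    min_targets: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift regulon targets' log2 means to encode TF activity.

    Each target gene of a spiked TF gets its log2 mean shifted by
    ``weight * a_f`` (so repressed targets, weight < 0, move opposite
    to the activity change), in the given samples (default: all).

    Parameters
    ----------
    eta
        Gene x sample log2-mean matrix (as passed to ``eta_modifier``).
    network
        Edge table with columns ``source, target, weight``.
    tf_shifts
        Map TF id -> activity shift ``a_f`` (log2 units per unit weight).
    samples
        Sample ids to modify; ``None`` means all columns.
    min_targets
        Minimum regulon targets that must be present among ``eta``'s
        genes for a TF to be spiked.

    Returns
    -------
    (modified eta, spike truth)
        The truth table has one row per spiked TF: ``tf, shift,
        n_targets``.
    """
    unknown = sorted(set(tf_shifts) - set(network["source"]))
    if unknown:
        raise ValueError(f"TFs absent from the network: {unknown}")
    cols = list(eta.columns) if samples is None else list(samples)
    missing_cols = sorted(set(cols) - set(eta.columns))
    if missing_cols:
        raise ValueError(f"samples absent from eta: {missing_cols}")
    out = eta.copy()
    records = []
    for tf, a_f in tf_shifts.items():
        edges = network[network["source"] == tf]
        present = edges[edges["target"].isin(out.index)]
        if len(present) < min_targets:
            raise ValueError(
                f"TF {tf!r} has {len(present)} targets in the gene list; "
                f"need >= {min_targets}"
            )
        shift = present.set_index("target")["weight"] * float(a_f)
        out.loc[shift.index, cols] = out.loc[shift.index, cols].add(shift, axis=0)
        records.append({"tf": tf, "shift": float(a_f), "n_targets": len(present)})
    return out, pd.DataFrame(records)
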