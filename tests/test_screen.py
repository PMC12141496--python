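"""Dose-correlation meta-analysis: transforms, pooling, and the screen."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from radscreen import (
    SimParams,
    bh_adjust,
    donor_correlations,
    fisher_z,
    inverse_fisher_z,
    pool_rubin,
    screen,
    simulate_counts,
)
from radscreen.screen import DonorCorrelation


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), abs=1e-12)

    def test_clamp_keeps_r_one_finite(self):
        assert fisher_z(1.0) == pytest.approx(math.atanh(1 - 1e-6))
        assert fisher_z(-1.0) == pytest.approx(-math.atanh(1 - 1e-6))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-0.999, 0.999))
    def test_round_trip(self, r):
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-9)


def _expr_from(design, fn):
    return pd.Series(
        [fn(row) for row in design.itertuples()], index=design["sample_id"]
    )


class TestDonorCorrelations:
    def test_expression_equal_to_dose_gives_r_one(self, design):
        expr = _expr_from(design, lambda row: row.dose_gy)
        corrs = donor_correlations(expr, design, 6.0)
        assert len(corrs) == 3
        assert all(c.r == pytest.approx(1.0) for c in corrs)
        assert all(c.n == 5 and c.var == 0.5 for c in corrs)

    def test_affine_negative_relation(self, design):
        expr = _expr_from(design, lambda row: -3.0 * row.dose_gy + 7.0)
        corrs = donor_correlations(expr, design, 2.0)
        assert all(c.r == pytest.approx(-1.0) for c in corrs)

    def test_hand_computed_pearson(self):
        # pairs (0,1),(0.5,2),(1,2),(2,4),(4,5): r = 10/sqrt(10*10.8)
        from radscreen import generate_design

        design = generate_design([("A", "male")], [0, 0.5, 1, 2, 4], [6])
        expr = pd.Series([1.0, 2.0, 2.0, 4.0, 5.0], index=design["sample_id"])
        (c,) = donor_correlations(expr, design, 6.0)
        assert c.r == pytest.approx(0.9622504486493764, abs=1e-12)

    def test_constant_expression_drops_donor(self, design):
        expr = _expr_from(
            design, lambda row: row.dose_gy if row.donor_id != "D2" else 3.0
        )
        with pytest.warns(UserWarning, match="D2"):
            corrs = donor_correlations(expr, design, 6.0)
        assert [c.donor_id for c in corrs] == ["D1", "D3"]

    def test_too_few_doses_rejected(self):
        from radscreen import generate_design

        design = generate_design([("A", "male")], [0, 1, 2], [6])
        expr = pd.Series([0.0, 1.0, 2.0], index=design["sample_id"])
        with pytest.raises(ValueError, match="4 distinct doses"):
            donor_correlations(expr, design, 6.0)


def _dc(z, n=5):
    return DonorCorrelation(
        donor_id="x", r=math.tanh(z), n=n, z=z, var=1.0 / (n - 3)
    )


class TestPoolRubin:
    def test_single_donor_reduction(self):
        with pytest.warns(UserWarning, match="single donor"):
            pc = pool_rubin([_dc(0.8)], include_between=True)
        assert pc.z_pooled == pytest.approx(0.8)
        assert pc.t_var == pytest.approx(0.5)
        assert pc.p == pytest.approx(2 * stats.norm.sf(0.8 / math.sqrt(0.5)))

    def test_identical_donors_no_between_variance(self):
        pc = pool_rubin([_dc(1.0), _dc(1.0), _dc(1.0)], include_between=True)
        assert pc.b == 0.0
        assert pc.t_var == pytest.approx(0.5)
        assert pc.z_pooled == pytest.approx(1.0)
        assert pc.r_pooled == pytest.approx(math.tanh(1.0), abs=1e-12)

    def test_between_variance_hand_arithmetic(self):
        pc = pool_rubin([_dc(0.5), _dc(1.0), _dc(1.5)], include_between=True)
        assert pc.z_pooled == pytest.approx(1.0)
        assert pc.w_bar == pytest.approx(0.5)
        assert pc.b == pytest.approx(0.25)
        assert pc.t_var == pytest.approx(0.5 + (4.0 / 3.0) * 0.25)
        # Barnard-Rubin df: (m-1) * (1 + W/((1+1/m) B))^2 = 2 * 2.5^2
        assert pc.df == pytest.approx(12.5)

    def test_pure_fixed_effects_variance(self):
        pc = pool_rubin([_dc(0.5), _dc(1.0), _dc(1.5)], include_between=False)
        assert pc.t_var == pytest.approx(0.5 / 3)
        assert math.isinf(pc.df)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([])

    def test_wider_confidence_never_narrows(self):
        corrs = [_dc(0.2), _dc(0.9), _dc(0.5)]
        lo95 = pool_rubin(corrs, conf=0.95)
        lo99 = pool_rubin(corrs, conf=0.99)
        assert lo99.ci_low <= lo95.ci_low
        assert lo99.ci_high >= lo95.ci_high

    def test_between_inclusion_never_narrows_under_heterogeneity(self):
        corrs = [_dc(0.2), _dc(0.9), _dc(0.5)]
        fe = pool_rubin(corrs, include_between=False)
        rb = pool_rubin(corrs, include_between=True)
        assert rb.ci_low <= fe.ci_low and rb.ci_high >= fe.ci_high


class TestBH:
    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    def test_monotone_and_dominates_p(self, ps):
        p = np.asarray(ps)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _inject_gene(counts, design, fn, name="GSPIKE"):
    """Append a deterministic gene derived from the design factors."""
    vals = [int(fn(row)) for row in design.itertuples()]
    out = counts.copy()
    out.loc[name] = vals
    return out


class TestScreen:
    def test_dose_proportional_gene_is_significant_positive(self, small_sim, design):
        counts, _ = small_sim
        counts = _inject_gene(
            counts, design, lambda row: round(2 ** (7.0 + row.dose_gy))
        )
        table = screen(counts, design, 6.0)
        row = table.loc["GSPIKE"]
        assert row["class"] == "significant_positive"
        assert row["r_pooled"] > 0.95

    def test_donor_offsets_and_scaling_change_nothing(self, small_sim, design):
        counts, _ = small_sim
        base = screen(counts, design, 6.0, log_scale=False, min_mean=0)
        # location/scale invariance of Pearson r holds on the raw
        # normalized scale; verify r columns are unchanged when the
        # expression of each donor is shifted after normalization
        from radscreen.preprocess import size_factors_median_of_ratios

        kept = counts
        expr = kept.div(size_factors_median_of_ratios(kept), axis=1)
        rs = {}
        for shift in (0.0, 50.0):
            r_cols = {}
            for donor, grp in design[design.time_h == 6.0].groupby("donor_id"):
                sub = expr[grp["sample_id"]] + shift
                doses = grp["dose_gy"].to_numpy(float)
                yc = sub.to_numpy() - sub.to_numpy().mean(1, keepdims=True)
                xc = doses - doses.mean()
                r_cols[donor] = (yc @ xc) / (
                    np.sqrt((yc**2).sum(1)) * np.sqrt((xc**2).sum())
                )
            rs[shift] = r_cols
        for donor in rs[0.0]:
            assert np.allclose(rs[0.0][donor], rs[50.0][donor], atol=1e-12)
        # and the screen's own r columns agree with the direct computation
        for donor in rs[0.0]:
            got = base[f"r_{donor}"].reindex(counts.index).to_numpy()
            assert np.allclose(got, rs[0.0][donor], atol=1e-10, equal_nan=True)

    def test_untestable_gene_is_flagged_not_fatal(self, design):
        rng = np.random.default_rng(8)
        # mostly constant rows pin every size factor at exactly 1, so
        # constancy survives normalization
        counts = pd.DataFrame(
            np.tile(rng.integers(50, 500, size=(21, 1)), (1, len(design))),
            index=[f"g{i}" for i in range(21)],
            columns=design["sample_id"],
        )
        for g in ("g1", "g2", "g3"):
            counts.loc[g] = rng.integers(50, 500, size=len(design))
        # constant expression at 6 h for two donors -> < 2 usable donors
        six = design[design.time_h == 6.0]
        for donor in ("D1", "D2"):
            cols = six.loc[six.donor_id == donor, "sample_id"]
            counts.loc["g0", cols] = 77
        cols3 = six.loc[six.donor_id == "D3", "sample_id"]
        counts.loc["g0", cols3] = rng.integers(50, 500, size=len(cols3))
        with pytest.warns(UserWarning, match="untestable"):
            table = screen(counts, design, 6.0, min_mean=0)
        assert table.loc["g0", "class"] == "untestable"
        assert np.isnan(table.loc["g0", "p"])
        # the genes with real variation are still tested
        assert (table.loc[["g1", "g2", "g3"], "class"] != "untestable").all()

    def test_matches_scalar_reference_path(self, small_sim, design):
        """Vectorized screen equals donor_correlations + pool_rubin per gene."""
        counts, _ = small_sim
        from radscreen.preprocess import (
            filter_low_expression,
            normalize_log,
            size_factors_median_of_ratios,
        )

        table = screen(counts, design, 6.0)
        kept = filter_low_expression(counts)
        expr = normalize_log(kept, size_factors_median_of_ratios(kept))
        rng = np.random.default_rng(0)
        for gene in rng.choice(expr.index, size=25, replace=False):
            corrs = donor_correlations(expr.loc[gene], design, 6.0)
            pc = pool_rubin(corrs)
            row = table.loc[gene]
            assert row["z_pooled"] == pytest.approx(pc.z_pooled, abs=1e-12)
            assert row["t_var"] == pytest.approx(pc.t_var, abs=1e-12)
            assert row["p"] == pytest.approx(pc.p, abs=1e-12)
            assert row["ci_low"] == pytest.approx(pc.ci_low, abs=1e-12)

    def test_sorted_by_absolute_pooled_r(self, small_sim, design):
        counts, _ = small_sim
        table = screen(counts, design, 6.0)
        r = table["r_pooled"].abs().to_numpy()
        r = r[~np.isnan(r)]
        assert np.all(np.diff(r) <= 1e-12)
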