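"""Articulatory-effort functional: laryngeal term, tract integral,
place asymmetries and the inter-closure-interval sweep."""

import numpy as np
import pandas as pd
import pytest

from ccvmotor.effort import (
    CCVSpec,
    EffortConfig,
    UnsupportedClusterError,
    analysis_ccvs,
    calibrate_e0,
    ccv_effort,
    ccv_from_string,
    devoicing_term,
    effort_sweep,
    effort_table,
    tract_effort,
)
from ccvmotor.tract_model import AreaField, parametric_geometry

VOICED = ["bda", "bga", "dba", "dga", "gba", "gda"]
DEVOICED = ["bca", "bta", "bpa", "dca", "dta", "dpa", "gca", "gta", "gpa"]


class TestCCVSpec:
    def test_repeated_consonant_rejected(self):
        with pytest.raises(ValueError):
            CCVSpec(c1="t", c2="t")

    def test_voicing_follows_consonant_identity(self):
        assert ccv_from_string("bda").voiced1 and ccv_from_string("bda").voiced2
        gta = ccv_from_string("gta")
        assert gta.voiced1 and not gta.voiced2

    def test_analysis_set_is_the_fifteen_voiced_initial_ccvs(self):
        labels = [c.label for c in analysis_ccvs()]
        assert len(labels) == 15
        assert set(labels) == set(VOICED) | set(DEVOICED)


class TestDevoicingTerm:
    @pytest.mark.parametrize("label", VOICED)
    def test_fully_voiced_ccvs_pay_nothing(self, label):
        assert devoicing_term(ccv_from_string(label), 2.5) == 0.0

    @pytest.mark.parametrize("label", DEVOICED)
    def test_devoiced_ccvs_pay_the_constant(self, label):
        assert devoicing_term(ccv_from_string(label), 2.5) == 2.5

    def test_zero_configuration_is_degenerate(self):
        assert devoicing_term(ccv_from_string("gta"), 0.0) == 0.0


class TestTractEffort:
    def test_neutral_field_has_zero_effort(self, geometry):
        from ccvmotor.tract_model import VowelGesture, area_function

        field = area_function(
            geometry, VowelGesture(0, 0, 0.5), [], np.linspace(0, 0.5, 11)
        )
        assert tract_effort(field) == 0.0

    def test_unit_offset_integrates_to_length_times_duration(self):
        geo = parametric_geometry(L=17.5, n=51)
        x, t = geo.x_grid, np.linspace(0, 0.49, 50)
        from ccvmotor.tract_model import neutral_area

        neutral = neutral_area(geo)
        field = AreaField(
            x_grid=x, t_grid=t, area=np.tile(neutral[:, None], (1, 50)) + 1.0,
            neutral=neutral,
        )
        assert tract_effort(field) == pytest.approx(17.5 * 0.49, rel=1e-12)

    def test_matches_midpoint_oracle_at_ten_x_resolution(self):
        # analytic field A = 2 + sin(x) cos(t) around neutral 2
        def build(nx, nt, midpoint=False):
            x = np.linspace(0, 3.0, nx)
            t = np.linspace(0, 2.0, nt)
            if midpoint:
                x = (x[:-1] + x[1:]) / 2
                t = (t[:-1] + t[1:]) / 2
            return x, t

        x, t = build(31, 31)
        field = AreaField(
            x_grid=x, t_grid=t,
            area=2.0 + np.sin(x)[:, None] * np.cos(t)[None, :],
            neutral=np.full_like(x, 2.0),
        )
        xm, tm = build(301, 301, midpoint=True)
        dev = np.abs(np.sin(xm)[:, None] * np.cos(tm)[None, :])
        oracle = dev.sum() * (xm[1] - xm[0]) * (tm[1] - tm[0])
        assert tract_effort(field) == pytest.approx(oracle, rel=5e-3)

    def test_halving_grid_steps_changes_effort_below_a_tenth_percent(self):
        coarse = ccv_effort(
            ccv_from_string("bda"), parametric_geometry(n=101),
            EffortConfig(E0_value=0.0, time_step=0.001),
        ).E_tract
        fine = ccv_effort(
            ccv_from_string("bda"), parametric_geometry(n=201),
            EffortConfig(E0_value=0.0, time_step=0.0005),
        ).E_tract
        assert abs(fine - coarse) / coarse < 1e-3

    def test_degenerate_grid_rejected(self):
        field = AreaField(
            x_grid=np.array([0.0]), t_grid=np.array([0.0]),
            area=np.zeros((1, 1)), neutral=np.zeros(1),
        )
        with pytest.raises(ValueError):
            tract_effort(field)


class TestCCVEffort:
    def test_laryngeal_term_is_additive(self, geometry):
        res = ccv_effort(ccv_from_string("gta"), geometry, EffortConfig(E0_value=1.7))
        assert res.E_total - res.E_tract == pytest.approx(1.7)

    def test_place_asymmetry_under_default_geometry(self, geometry):
        e = effort_table(geometry=geometry).set_index("ccv")["E_total"]
        assert e["bda"] < e["dba"]
        assert e["bga"] < e["gba"]
        assert e["dga"] < e["gda"]

    def test_devoiced_group_mean_exceeds_voiced_for_positive_e0(self, geometry):
        tab = effort_table(geometry=geometry).set_index("ccv")["E_total"]
        assert tab[DEVOICED].mean() > tab[VOICED].mean()

    def test_calibrated_e0_realizes_the_group_ratio(self, geometry):
        tab = effort_table(geometry=geometry).set_index("ccv")["E_total"]
        assert tab[DEVOICED].mean() / tab[VOICED].mean() == pytest.approx(
            41.3 / 38.2, rel=1e-9
        )
        assert calibrate_e0(geometry) > 0

    def test_closure_interval_must_fit_in_utterance(self, geometry):
        with pytest.raises(ValueError):
            ccv_effort(ccv_from_string("bda"), geometry, EffortConfig(dt_closure=0.6))

    def test_fricative_clusters_unsupported(self, geometry):
        with pytest.raises(UnsupportedClusterError):
            ccv_effort(ccv_from_string("sda"), geometry)


class TestEffortTable:
    def test_fifteen_analysis_ccvs_give_fifteen_rows(self, geometry):
        assert len(effort_table(geometry=geometry)) == 15

    def test_empty_input_gives_empty_table(self, geometry):
        assert len(effort_table([], geometry, EffortConfig(E0_value=0.0))) == 0

    def test_bit_for_bit_determinism(self, geometry):
        a = effort_table(geometry=geometry)
        b = effort_table(geometry=geometry)
        pd.testing.assert_frame_equal(a, b)

    def test_positive_effort_tau_association_across_the_sweep(
        self, geometry, calibration
    ):
        from scipy.stats import spearmanr

        sweep = effort_sweep(geometry=geometry)
        for _, group in sweep.groupby("dt_closure"):
            tau = group["ccv"].map(calibration.tau_mean)
            rho, _ = spearmanr(group["E_total"], tau)
            assert rho > 0
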