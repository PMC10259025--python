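"""Unit and property tests for the coupling formula chain and its solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bisect_descending, fixed_point_root, residual_direct
from vacef import (
    BeatRecord,
    CouplingConstants,
    SolverSettings,
    beat_to_ef,
    coupling_residual,
    ef_from_efficiency,
    efficiency_from_coupling,
    estimate_pes,
    k_from_coupling,
    pmax_hypothetical,
    solve_coupling,
)
from vacef.errors import DomainError, InvalidInputError, NoSolutionError

# larger root at the cohort-mean inputs, frozen from the fixed-point oracle
X_TABLE1 = 1.3676255615038


class TestEstimatePes:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (119.0, 72.0, 89.4724),   # cohort means
            (120.0, 80.0, 96.8614),   # hand arithmetic: 24.6 + 71.84 + 0.4214
        ],
    )
    def test_regression_values(self, sbp, dbp, expected):
        assert estimate_pes(sbp, dbp) == pytest.approx(expected, abs=1e-10)

    def test_lies_between_cuff_pressures_for_physiological_inputs(self):
        for sbp, dbp in [(119, 72), (100, 60), (140, 90), (160, 95)]:
            pes = estimate_pes(sbp, dbp)
            assert dbp < pes < sbp

    @pytest.mark.parametrize("sbp,dbp", [(100, 100), (90, 100), (100, 0), (100, -5)])
    def test_invalid_pressures_rejected(self, sbp, dbp):
        with pytest.raises(InvalidInputError):
            estimate_pes(sbp, dbp)


class TestSlopeRatio:
    def test_unit_base(self):
        assert k_from_coupling(1.0) == pytest.approx(0.53, abs=1e-15)

    def test_worked_value(self):
        assert k_from_coupling(1.3677) == pytest.approx(0.6218, abs=5e-4)

    @pytest.mark.parametrize("x", [0.0, -1.0])
    def test_domain_error(self, x):
        with pytest.raises(DomainError):
            k_from_coupling(x)

    @given(st.floats(min_value=0.05, max_value=20.0), st.floats(min_value=0.05, max_value=20.0))
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert k_from_coupling(lo) < k_from_coupling(hi)


class TestResidual:
    def test_value_at_unit_coupling(self):
        # 0.80472*(1 + 0.53*303/97) - 2
        g = coupling_residual(1.0, pad=72, pes=89.4724, et=303, pep=97)
        assert g == pytest.approx(0.137, abs=1e-3)

    def test_near_zero_at_oracle_root(self):
        g = coupling_residual(X_TABLE1, pad=72, pes=89.4724, et=303, pep=97)
        assert abs(g) < 1e-10

    def test_matches_direct_evaluation(self, rng):
        for _ in range(50):
            x = rng.uniform(0.1, 5)
            pad = rng.uniform(50, 100)
            pes = pad * rng.uniform(1.05, 1.6)
            et = rng.uniform(200, 400)
            pep = rng.uniform(60, 150)
            assert coupling_residual(x, pad, pes, et, pep) == pytest.approx(
                residual_direct(x, pad, pes, et, pep), abs=1e-14
            )

    def test_concavity_on_positive_axis(self):
        # second central difference of a strictly concave function is negative
        xs = np.linspace(0.05, 20, 500)
        g = np.array([coupling_residual(x, 72, 89.4724, 303, 97) for x in xs])
        assert np.all(np.diff(g, 2) < 0)


class TestPmax:
    def test_worked_value_and_coupling_identity(self):
        k = k_from_coupling(X_TABLE1)
        pmax = pmax_hypothetical(pad=72, k=k, et=303, pep=97)
        assert pmax == pytest.approx(211.8, abs=0.1)
        # peak-pressure identity: (pmax - pes)/pes recovers the coupling ratio
        assert (pmax - 89.4724) / 89.4724 == pytest.approx(X_TABLE1, abs=1e-9)

    def test_zero_slope_returns_pad(self):
        assert pmax_hypothetical(85.0, 0.0, 300, 100) == 85.0

    def test_unit_ratio_doubles(self):
        assert pmax_hypothetical(100.0, 1.0, 250.0, 250.0) == pytest.approx(200.0)


class TestEfficiencyChain:
    @pytest.mark.parametrize(
        "x,expected",
        [(1.0, 2.0 / 3.0), (1.3677, 0.7323)],
    )
    def test_efficiency_values(self, x, expected):
        assert efficiency_from_coupling(x) == pytest.approx(expected, abs=1e-4)

    def test_efficiency_limit(self):
        assert efficiency_from_coupling(1e9) > 1 - 1e-9

    @pytest.mark.parametrize(
        "eff,expected",
        [(2.0 / 3.0, 0.5), (1.0, 1.0), (0.7323, 0.5777)],
    )
    def test_ef_values(self, eff, expected):
        assert ef_from_efficiency(eff) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_ef_domain(self, bad):
        with pytest.raises(DomainError):
            ef_from_efficiency(bad)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_closed_form_equivalence(self, x):
        """EF(Eff(x)) collapses to x/(1+x): the V0=0 loop algebra in one line."""
        ef = ef_from_efficiency(efficiency_from_coupling(x))
        assert ef == pytest.approx(x / (1.0 + x), abs=1e-12)

    def test_ef_below_efficiency(self):
        for eff in np.linspace(0.05, 0.95, 19):
            assert ef_from_efficiency(eff) < eff


class TestSolveCoupling:
    def test_table1_root(self, table1_beat):
        est = solve_coupling(table1_beat)
        assert est.converged
        assert est.ees_over_ea == pytest.approx(X_TABLE1, abs=1e-8)
        assert est.pes == pytest.approx(89.4724, abs=1e-10)
        assert abs(est.residual) <= 1e-10

    def test_peak_pressure_consistency(self, table1_beat):
        est = solve_coupling(table1_beat)
        assert (est.pmax - est.pes) / est.pes == pytest.approx(
            est.ees_over_ea, abs=1e-9
        )

    def test_agrees_with_fixed_point_oracle(self, rng):
        checked = 0
        for _ in range(200):
            pep = rng.uniform(60, 150)
            et = rng.uniform(200, 400)
            dbp = rng.uniform(55, 95)
            sbp = dbp + rng.uniform(20, 70)
            beat = BeatRecord(pep=pep, et=et, sbp=sbp, dbp=dbp)
            pes = estimate_pes(sbp, dbp)
            if bisect_descending(dbp, pes, et, pep) is None:
                continue  # genuinely rootless beat, covered below
            est = solve_coupling(beat)
            oracle = fixed_point_root(dbp, est.pes, et, pep)
            assert est.ees_over_ea == pytest.approx(oracle, abs=1e-8)
            checked += 1
        assert checked > 100

    def test_agrees_with_bisection_oracle(self, rng):
        """Newton matches bisection where a root exists; both agree a beat is
        rootless otherwise."""
        checked = 0
        for _ in range(200):
            pep = rng.uniform(60, 150)
            et = rng.uniform(200, 400)
            dbp = rng.uniform(55, 95)
            sbp = dbp + rng.uniform(20, 70)
            beat = BeatRecord(pep=pep, et=et, sbp=sbp, dbp=dbp)
            oracle = bisect_descending(dbp, estimate_pes(sbp, dbp), et, pep)
            if oracle is None:
                with pytest.raises(NoSolutionError):
                    solve_coupling(beat)
                continue
            est = solve_coupling(beat)
            assert est.ees_over_ea == pytest.approx(oracle, abs=1e-8)
            checked += 1
        assert checked > 100

    def test_round_trip_by_construction(self):
        from vacef import timing_from_truth

        beat = timing_from_truth(2.0, pep=97, sbp=119, dbp=72)
        est = solve_coupling(beat)
        assert est.ees_over_ea == pytest.approx(2.0, abs=1e-8)

    def test_no_solution_when_ejection_too_short(self):
        # pad/pes = 0.5 and tiny et/pep keep g negative everywhere
        beat = BeatRecord(pep=100, et=30, sbp=266.7, dbp=50)
        pes = estimate_pes(beat.sbp, beat.dbp)
        xs = np.logspace(-6, 3, 2000)
        assert all(residual_direct(x, 50, pes, 30, 100) < 0 for x in xs)
        with pytest.raises(NoSolutionError):
            solve_coupling(beat)

    def test_pad_at_least_pes_flagged_not_failed(self):
        # constants that push pes below dbp: single-root regime
        constants = CouplingConstants(pes_a=0.1, pes_b=0.5, pes_c=0.0)
        beat = BeatRecord(pep=100, et=300, sbp=120, dbp=80)
        est = solve_coupling(beat, constants)
        assert est.converged
        assert any("suspect" in w for w in est.warnings)
        assert abs(
            coupling_residual(est.ees_over_ea, 80, est.pes, 300, 100, constants)
        ) <= 1e-10

    @pytest.mark.parametrize("param,direction", [("et", +1), ("pad", +1), ("pep", -1)])
    def test_monotonicity_of_solution(self, param, direction):
        """Longer ejection or higher diastolic pressure raises the solved
        coupling; longer pre-ejection lowers it."""
        base = dict(pep=97.0, et=303.0, sbp=119.0, dbp=72.0)
        grid = {
            "et": np.linspace(250, 380, 8),
            "pad": np.linspace(60, 85, 8),
            "pep": np.linspace(70, 140, 8),
        }[param]
        values = []
        for v in grid:
            kw = dict(base)
            if param == "pad":
                # move dbp while keeping sbp comfortably above it
                kw["dbp"] = v
                kw["sbp"] = 140.0
            else:
                kw[param] = v
            values.append(solve_coupling(BeatRecord(**kw)).ees_over_ea)
        diffs = np.diff(values) * direction
        assert np.all(diffs > 0)


class TestBeatToEf:
    def test_table1_full_pipeline(self, table1_beat):
        est = beat_to_ef(table1_beat)
        assert est.eff == pytest.approx(0.7323, abs=5e-4)
        assert 100 * est.ef == pytest.approx(57.76, abs=0.05)

    def test_unit_coupling_round_trip(self):
        from vacef import timing_from_truth

        beat = timing_from_truth(1.0, pep=97, sbp=119, dbp=72)
        est = beat_to_ef(beat)
        assert est.ef == pytest.approx(0.5, abs=1e-8)

    def test_invalid_beat_rejected(self):
        with pytest.raises(InvalidInputError) as err:
            BeatRecord(pep=0, et=300, sbp=120, dbp=80)
        assert "pep" in str(err.value)

    def test_error_annotated_with_beat_id(self):
        beat = BeatRecord(pep=100, et=30, sbp=266.7, dbp=50, id="bad-beat")
        with pytest.raises(NoSolutionError, match="bad-beat"):
            beat_to_ef(beat)


class TestSettingsValidation:
    def test_bracket_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            SolverSettings(bracket_low=2.0, bracket_high=1.0)

    def test_concavity_exponent_enforced(self):
        with pytest.raises(InvalidInputError):
            CouplingConstants(p_k=1.2)


@settings(deadline=None, max_examples=50)
@given(
    x=st.floats(min_value=0.3, max_value=5.0),
    pep=st.floats(min_value=60, max_value=150),
    dbp=st.floats(min_value=55, max_value=95),
    pulse=st.floats(min_value=20, max_value=70),
)
def test_round_trip_recovery_property(x, pep, dbp, pulse):
    """A beat constructed from a known coupling ratio solves back to it."""
    import warnings

    from vacef import timing_from_truth

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beat = timing_from_truth(x, pep=pep, sbp=dbp + pulse, dbp=dbp)
    est = solve_coupling(beat)
    assert est.ees_over_ea == pytest.approx(x, abs=1e-8)
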