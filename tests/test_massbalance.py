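"""The four-process mass-balance inversion, Monte Carlo, and scenarios."""

import numpy as np
import pytest

from n2opart import (
    CollinearityError,
    InfeasibleSolutionError,
    MissingMeasurementError,
    ProcessFractions,
    ScenarioSpec,
    amo_dd15N,
    build_system,
    builtin_scenarios,
    clip_renormalize,
    default_endmember_set,
    forward_model,
    partition_core,
    run_monte_carlo,
    run_scenarios,
    solve_fractions,
)
from n2opart.exceptions import ConfigurationError, InvalidValueError
from n2opart.massbalance import Endmember, EndmemberSet
from n2opart.synthetic import default_truth, generate_steady_record

from conftest import random_feasible_truth


def truth_pf(fracs, f_red=0.0, processes=("bDNF", "fDNF", "AMO", "nDNF")):
    return ProcessFractions(processes=processes, fractions=tuple(fracs),
                            f_red=f_red)


class TestAmoDd15N:
    def test_identical_pools_no_fractionation(self):
        assert amo_dd15N(8.0, 8.0, 0.0) == 0.0

    def test_published_means(self):
        # NO3 4.6, TRN 11.9, NH3->N2O eps 3.7 permil
        assert amo_dd15N(4.6, 11.9, 3.7) == pytest.approx(-3.6)

    def test_linear_in_eps(self):
        base = amo_dd15N(5.0, 12.0, 3.7)
        assert amo_dd15N(5.0, 12.0, 3.7 + 2.5) == pytest.approx(base + 2.5)

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidValueError):
            amo_dd15N(float("nan"), 0.0, 0.0)


class TestBuildSystem:
    MEAS = {"dd15N_meas": 4.6, "SP_meas": 16.2, "o_ratio_meas": 0.765}

    def test_default_endmembers_full_rank(self, ems):
        A, b, procs = build_system(self.MEAS, ems.with_amo_dd15N(4.6, 11.9), 0.1)
        assert np.linalg.matrix_rank(A) == 4
        assert procs == ("bDNF", "fDNF", "AMO", "nDNF")

    def test_duplicate_endmembers_collinear(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        dup = resolved.with_overrides(
            {"fDNF": {"dd15N": resolved.get("bDNF").dd15N,
                      "SP": resolved.get("bDNF").SP,
                      "o_transfer": resolved.get("bDNF").o_transfer}})
        with pytest.raises(CollinearityError, match="bDNF.*fDNF"):
            build_system(self.MEAS, dup, 0.1)

    def test_reduction_shifts_sp_row(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        _, b0, _ = build_system(self.MEAS, resolved, 0.0)
        _, b9, _ = build_system(self.MEAS, resolved, 0.9)
        # sp_eps_red = -6: at 90% reduction the production mixture must
        # explain an SP 5.4 permil lower than measured
        assert b9[3] == pytest.approx(b0[3] - 5.4)
        # the oxygen-anomaly row is invariant to reduction
        assert b9[1] == pytest.approx(b0[1])
        assert b9[2] == pytest.approx(b0[2])  # n15_eps_red defaults to 0


class TestSolveFractions:
    def test_vertex_recovery(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        for i, proc in enumerate(resolved.processes):
            fracs = [0.0] * 4
            fracs[i] = 1.0
            meas = forward_model(truth_pf(fracs), resolved)
            out = solve_fractions(build_system(meas, resolved, 0.0))
            assert out.fractions[i] == pytest.approx(1.0, abs=1e-10)
            assert out.feasible

    def test_interior_round_trip(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        meas = forward_model(truth_pf([0.25] * 4, f_red=0.3), resolved)
        out = solve_fractions(build_system(meas, resolved, 0.3), f_red=0.3)
        assert np.allclose(out.fractions, 0.25, atol=1e-10)
        assert out.residual_norm < 1e-9

    def test_matches_simplex_grid_oracle_on_small_sample(self, ems):
        """Spot check against brute-force grid search (full run in the
        acceptance suite)."""
        from test_acceptance import simplex_grid, grid_oracle
        rng = np.random.default_rng(123)
        G = simplex_grid(0.01)
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        for _ in range(5):
            truth = random_feasible_truth(rng, resolved.processes, 0.1)
            meas = forward_model(truth, resolved)
            A, b, _ = build_system(meas, resolved, 0.1)
            x = solve_fractions((A, b, resolved.processes), 0.1).fractions
            best = grid_oracle(A, b, G)
            assert np.max(np.abs(best - np.asarray(x))) <= 0.02

    def test_infeasibility_flagged_outside_simplex(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        # oxygen-anomaly ratio above the maximum attainable sum f_i*o_i = 1
        meas = {"dd15N_meas": 4.6, "SP_meas": 16.2, "o_ratio_meas": 1.5}
        out = solve_fractions(build_system(meas, resolved, 0.0))
        assert not out.feasible
        assert min(out.fractions) < 0


class TestClipRenormalize:
    def test_forced_arithmetic(self):
        pf = truth_pf([0.5, 0.6, -0.1, 0.0])
        out = clip_renormalize(pf)
        assert out.fractions == pytest.approx((0.4545, 0.5455, 0.0, 0.0), abs=1e-4)

    def test_feasible_input_unchanged_and_idempotent(self):
        pf = truth_pf([0.4, 0.3, 0.2, 0.1])
        out = clip_renormalize(pf)
        assert out.fractions == pytest.approx(pf.fractions)
        again = clip_renormalize(out)
        assert again.fractions == pytest.approx(out.fractions)

    def test_always_on_simplex(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            raw = rng.normal(0.25, 0.5, 4)
            if np.all(raw <= 0):
                continue
            out = clip_renormalize(truth_pf(tuple(raw)))
            assert min(out.fractions) >= 0.0
            assert sum(out.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_all_nonpositive_is_infeasible(self):
        with pytest.raises(InfeasibleSolutionError):
            clip_renormalize(truth_pf([-0.2, -0.1, 0.0, -0.5]))


class TestForwardModel:
    def test_pure_fungal_sp(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        meas = forward_model(truth_pf([0, 1, 0, 0]), resolved)
        assert meas["SP_meas"] == pytest.approx(37.0)

    def test_pure_amo_no_anomaly_transfer(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        meas = forward_model(truth_pf([0, 0, 1, 0]), resolved)
        assert meas["o_ratio_meas"] == pytest.approx(0.0)

    def test_reduction_raises_sp(self, ems):
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        rng = np.random.default_rng(4)
        for _ in range(10):
            f = tuple(rng.dirichlet([1.0] * 4))
            sp = [forward_model(truth_pf(f, f_red=fr), resolved)["SP_meas"]
                  for fr in (0.0, 0.3, 0.9)]
            assert sp[0] < sp[1] < sp[2]

    def test_infeasible_truth_rejected(self, ems):
        with pytest.raises(InvalidValueError):
            forward_model(truth_pf([0.5, 0.7, -0.2, 0.0]),
                          ems.with_amo_dd15N(4.6, 11.9))


class TestPartitionCore:
    def test_exact_recovery_at_zero_noise(self, ems, noiseless_hn_truth):
        rec = generate_steady_record(noiseless_hn_truth, ems, seed=0)
        pf = partition_core(rec, ems, 0.1)
        assert np.allclose(pf.fractions, noiseless_hn_truth.fractions.fractions,
                           atol=1e-9)

    def test_missing_field_named(self, ems, ln_record):
        with pytest.raises(MissingMeasurementError, match="cap17O"):
            partition_core(ln_record, ems, 0.1)

    def test_published_hn_means_rank_fungal_high(self, ems, hn_record):
        """On the published high-nitrate treatment means, fungal
        denitrification is the largest or second-largest contributor."""
        for f_red in (0.1, 0.9):
            pf = partition_core(hn_record, ems, f_red)
            rank = sorted(pf.as_dict(), key=pf.as_dict().get, reverse=True)
            assert "fDNF" in rank[:2]

    def test_monotone_sp_response(self, ems, hn_record):
        """Raising measured SP (all else fixed) never decreases the clipped
        total of the high-SP processes (fDNF + AMO)."""
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        prev = -1.0
        for sp_meas in np.linspace(5.0, 35.0, 13):
            meas = {"dd15N_meas": 4.6, "SP_meas": float(sp_meas),
                    "o_ratio_meas": 0.765}
            raw = solve_fractions(build_system(meas, resolved, 0.1), 0.1)
            out = clip_renormalize(raw)
            total = out["fDNF"] + out["AMO"]
            assert total >= prev - 1e-9
            prev = total


class TestRunMonteCarlo:
    @staticmethod
    def _degenerate_ems(ems):
        from dataclasses import replace
        zeroed = tuple(replace(e, dd15N_sd=0.0, SP_sd=0.0) for e in ems.endmembers)
        return replace(ems, endmembers=zeroed, amo_eps_sd=0.0)

    @staticmethod
    def _record_with_zero_sds(ems):
        from n2opart import IsotopeComposition, PoolMeasurement, SteadyStateRecord
        resolved = ems.with_amo_dd15N(4.6, 11.9)
        meas = forward_model(truth_pf((0.45, 0.36, 0.12, 0.07), f_red=0.1),
                             resolved)
        eff = {
            "NO3": PoolMeasurement("NO3", isotopes=IsotopeComposition(
                d15N_bulk=4.6, sd={"d15N_bulk": 0.0})),
            "NO2": PoolMeasurement("NO2", isotopes=IsotopeComposition(
                cap17O=8.5, sd={"cap17O": 0.0})),
            "TRN": PoolMeasurement("TRN", isotopes=IsotopeComposition(
                d15N_bulk=11.9, sd={"d15N_bulk": 0.0})),
            "N2O": PoolMeasurement("N2O", isotopes=IsotopeComposition(
                d15N_bulk=4.6 - meas["dd15N_meas"], SP=meas["SP_meas"],
                cap17O=meas["o_ratio_meas"] * 8.5,
                sd={"d15N_bulk": 0.0, "SP": 0.0, "cap17O": 0.0})),
        }
        return SteadyStateRecord("zero-sd", "HN", effluent=eff)

    def test_zero_sd_collapses_to_point_estimate(self, ems):
        """Degenerate Gaussians: every draw equals the point estimate."""
        rec = self._record_with_zero_sds(ems)
        ems0 = self._degenerate_ems(ems)
        mc = run_monte_carlo(rec, ems0, 0.1, n_draws=500, seed=3)
        point = partition_core(rec, ems0, 0.1)
        assert np.allclose(mc.mean, point.fractions, atol=1e-12)
        assert np.allclose(mc.sd, 0.0, atol=1e-12)
        assert mc.infeasible_fraction == 0.0

    def test_reproducible_under_fixed_seed(self, ems, hn_record):
        a = run_monte_carlo(hn_record, ems, 0.1, n_draws=500, seed=11)
        b = run_monte_carlo(hn_record, ems, 0.1, n_draws=500, seed=11)
        assert a == b
        c = run_monte_carlo(hn_record, ems, 0.1, n_draws=500, seed=12)
        assert a.mean != c.mean

    def test_summary_shape_and_ordering(self, ems, hn_record):
        mc = run_monte_carlo(hn_record, ems, 0.1, n_draws=1000, seed=0)
        for i in range(4):
            assert mc.q025[i] <= mc.q500[i] <= mc.q975[i]
            assert 0.0 <= mc.mean[i] <= 1.0
        assert 0.0 <= mc.infeasible_fraction < 0.5
        assert not mc.high_infeasibility

    def test_rejects_too_few_draws(self, ems, hn_record):
        with pytest.raises(ConfigurationError):
            run_monte_carlo(hn_record, ems, 0.1, n_draws=50, seed=0)

    def test_missing_sd_is_an_error(self, ems):
        truth = default_truth("c", "HN")
        rec = generate_steady_record(truth, ems, seed=0)
        from dataclasses import replace
        from n2opart import IsotopeComposition, PoolMeasurement
        eff = dict(rec.effluent)
        pm = eff["N2O"]
        eff["N2O"] = PoolMeasurement("N2O", pm.concentration,
                                     isotopes=IsotopeComposition(
                                         d15N_bulk=pm.isotopes.d15N_bulk,
                                         SP=pm.isotopes.SP,
                                         cap17O=pm.isotopes.cap17O))
        rec2 = replace(rec, effluent=eff)
        with pytest.raises(MissingMeasurementError, match="s.d."):
            run_monte_carlo(rec2, ems, 0.1, n_draws=500, seed=0)


class TestScenarios:
    def test_empty_override_equals_base(self, ems, hn_record):
        table = run_scenarios(hn_record, ems,
                              [ScenarioSpec("base"), ScenarioSpec("copy")],
                              f_red_values=(0.1,))
        base = table[table.scenario == "base"].iloc[0]
        copy = table[table.scenario == "copy"].iloc[0]
        for p in ("bDNF", "fDNF", "AMO", "nDNF"):
            assert base[f"f_{p}"] == pytest.approx(copy[f"f_{p}"])

    def test_builtin_scenarios_cover_the_classic_knobs(self):
        names = {s.name for s in builtin_scenarios()}
        assert {"base", "nDNF_dd15N_28", "nDNF_dd15N_14", "fDNF_SP_30.3",
                "nDNF_o_transfer_1", "case2_cDNF"} == names

    def test_lower_fungal_sp_raises_fungal_share(self, ems, hn_record):
        table = run_scenarios(hn_record, ems, f_red_values=(0.1,))
        get = lambda s: table[table.scenario == s].iloc[0]
        assert get("fDNF_SP_30.3")["f_fDNF"] > get("base")["f_fDNF"]

    def test_ndnf_anomalous_substrate_shifts_amo_up_fdnf_down(self, ems, hn_record):
        table = run_scenarios(hn_record, ems, f_red_values=(0.1,))
        get = lambda s: table[table.scenario == s].iloc[0]
        assert get("nDNF_o_transfer_1")["f_AMO"] > get("base")["f_AMO"]
        assert get("nDNF_o_transfer_1")["f_fDNF"] < get("base")["f_fDNF"]

    def test_lower_ndnf_dd15n_raises_ndnf_share(self, ems, hn_record):
        table = run_scenarios(hn_record, ems, f_red_values=(0.1,))
        get = lambda s: table[table.scenario == s].iloc[0]
        assert (get("base")["f_nDNF"] < get("nDNF_dd15N_28")["f_nDNF"]
                < get("nDNF_dd15N_14")["f_nDNF"])

    def test_case2_uses_chemodenitrification(self, ems, hn_record):
        table = run_scenarios(hn_record, ems, f_red_values=(0.1,))
        row = table[table.scenario == "case2_cDNF"].iloc[0]
        assert np.isfinite(row["f_cDNF"])
        assert np.isnan(row.get("f_fDNF", float("nan")))


class TestEndmemberSetValidation:
    def test_requires_exactly_one_dnf_variant(self):
        ems = default_endmember_set("fDNF")
        both = (ems.get("bDNF"), ems.get("fDNF"),
                Endmember("cDNF", 0.0, 16.0, 1.0), ems.get("nDNF"))
        with pytest.raises(ConfigurationError):
            EndmemberSet(endmembers=both)

    def test_o_transfer_bounds(self):
        with pytest.raises(ConfigurationError):
            Endmember("bDNF", 0.0, -5.0, 1.5)

    def test_override_of_inactive_process_rejected(self, ems):
        with pytest.raises(ConfigurationError):
            ems.with_overrides({"cDNF": {"SP": 20.0}})
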