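"""Damage classification, correlation, ensembles and sweeps."""

import numpy as np
import pandas as pd
import pytest

from ventnet import (
    VentilatorProtocol,
    build_network,
    damage_report,
    run_ensemble,
    simulate,
    stiffness_damage_correlation,
    sweep,
    summarise_sweep,
)


def _handmade_result(g_values, started):
    """Minimal SimResult stand-in carrying only the fields damage_report reads."""

    class R:
        airways = pd.DataFrame(
            {
                "id": np.arange(len(g_values)),
                "generation": 16,
                "G_max": g_values,
                "t_start_s": [0.0 if s else np.nan for s in started],
            }
        )

    return R()


class TestDamageReport:
    def test_direct_threshold_comparison(self):
        res = _handmade_result([1e3, 1e4], [True, True])
        rep = damage_report(res, threshold=10**3.5)
        assert rep.per_airway["damaged"].sum() == 1
        assert rep.G_net == 1e4

    def test_infinite_threshold_flags_nothing(self, baseline_results):
        _, res = baseline_results[0]
        rep = damage_report(res, threshold=np.inf)
        assert rep.per_airway["damaged"].sum() == 0

    def test_unrecruited_airways_not_assessed(self):
        res = _handmade_result([5.0, 0.0, 7.0], [True, False, True])
        rep = damage_report(res, threshold=1.0)
        row = rep.per_airway.iloc[1]
        assert not row["assessed"] and not row["damaged"]
        assert np.isnan(row["relative"])
        assert rep.per_airway["relative"].dropna().mean() == pytest.approx(1.0)

    def test_relative_damage_averages_to_one_per_generation(self, baseline_results):
        _, res = baseline_results[0]
        rep = damage_report(res)
        means = rep.per_airway.groupby("generation")["relative"].mean()
        np.testing.assert_allclose(means, 1.0, rtol=1e-12)

    def test_peripheral_generation_sustains_the_network_maximum(
        self, baseline_results
    ):
        for _, res in baseline_results:
            rep = damage_report(res)
            df = rep.per_airway
            assert df.loc[df["G_max"].idxmax(), "generation"] == 16


def _clone(res):
    """Shallow stand-in carrying an independent copy of the airway table."""

    class R:
        airways = res.airways.copy()

    return R()


class TestStiffnessDamageCorrelation:
    def test_perfect_correlation_on_constructed_data(self, baseline_results):
        # assess only the terminal generation so relative damage is an
        # affine image of the recorded stress, then tie it to stiffness
        net, res = baseline_results[0]
        from ventnet import stiffness

        gams = np.array(
            [stiffness(a.reopening.a_init, a.elastica) for a in net.airways]
        )
        r2 = _clone(res)
        r2.airways.loc[r2.airways["generation"] != 16, "t_start_s"] = np.nan
        r2.airways["G_max"] = gams
        assert stiffness_damage_correlation(r2, net) == pytest.approx(1.0)
        r2.airways["G_max"] = gams.max() * 2 - gams
        assert stiffness_damage_correlation(r2, net) == pytest.approx(-1.0)

    def test_degenerate_variance_returns_nan(self, baseline_results):
        net, res = baseline_results[1]
        r2 = _clone(res)
        r2.airways["G_max"] = 1.0
        assert np.isnan(stiffness_damage_correlation(r2, net))

    def test_weak_correlation_across_conditions(self):
        # C x d grid of single recruitment events: stiffness is not a strong
        # predictor of relative damage.  At modest heterogeneity the
        # coefficients sit near zero; at d = 0.5 the stiffest late openers
        # bias the coefficient upward but never to a strong correlation.
        for C in (0.1, 0.5, 1.0):
            for d, bound in ((0.2, 0.3), (0.5, 0.7)):
                rs = []
                for seed in (1, 2, 3):
                    net = build_network(d, C, seed=seed)
                    rs.append(stiffness_damage_correlation(simulate(net), net))
                rs = np.array(rs)
                assert np.isfinite(rs).all()
                assert np.all(np.abs(rs) < bound), f"C={C}, d={d}: {rs}"


class TestEnsembles:
    def test_single_run_has_zero_spread(self):
        ens = run_ensemble(1, seed_base=0, collapse_C=0.1, heterogeneity_d=0.2)
        sd = ens.summary.set_index("quantity")["sd"]
        assert (sd.fillna(0.0) == 0.0).all()

    def test_reproducible_given_seed_base(self):
        a = run_ensemble(4, 10, 0.1, 0.2).runs
        b = run_ensemble(4, 10, 0.1, 0.2).runs
        pd.testing.assert_frame_equal(a, b)

    def test_envelopes_on_common_grid(self):
        ens = run_ensemble(
            3, 0, 0.1, 0.2, envelopes=True, envelope_points=50
        )
        env = ens.envelopes
        assert len(env) == 50
        assert (env["P_sd"] >= 0).all()
        assert env["n_recruited_mean"].iloc[-1] == pytest.approx(63.0)

    def test_baseline_mean_recruitment_time_within_bound(self):
        ens = run_ensemble(20, 0, 0.1, 0.2)
        assert ens.runs["complete"].all()
        assert ens.runs["t_R"].mean() <= 0.04

    def test_incomplete_runs_bookkept_truthfully(self):
        proto = VentilatorProtocol(v_t_per_kg=0.15)
        ens = run_ensemble(3, 0, 1.0, 0.2, proto)
        assert (~ens.runs["complete"]).all()
        assert (ens.runs["n_acini_open"] < 32).all()
        assert (ens.runs["termination"] == "incomplete_recruitment").all()


N_TREND = 30


@pytest.fixture(scope="module")
def grid():
    tidy = sweep(
        v_t_values=(4, 8, 12, 16),
        collapse_values=(0.1, 0.2, 0.5, 1.0),
        d_values=(0.2,),
        n=N_TREND,
        seed_base=0,
    )
    return summarise_sweep(tidy)


class TestSweepTrends:

    def test_recruitment_faster_at_larger_tidal_volume(self, grid):
        for c, block in grid.groupby("collapse_C"):
            t = block.sort_values("v_t_per_kg")["t_R_mean"].to_numpy()
            assert np.all(np.diff(t) < 0), f"C={c}: {t}"

    def test_recruitment_faster_for_more_collapsed_networks(self, grid):
        for vt, block in grid.groupby("v_t_per_kg"):
            t = block.sort_values("collapse_C")["t_R_mean"].to_numpy()
            assert np.all(np.diff(t) > 0), f"V_T={vt}: {t}"

    def test_tip_stress_rises_with_degree_of_collapse(self, grid):
        for vt, block in grid.groupby("v_t_per_kg"):
            g = block.sort_values("collapse_C")["G_net_mean"].to_numpy()
            assert np.all(np.diff(g) < 0), f"V_T={vt}: {g}"

    def test_peep_trades_speed_for_stress(self):
        tidy = sweep(
            v_t_values=(10,),
            collapse_values=(0.1, 0.5, 1.0),
            d_values=(0.2,),
            peep_values=(2.0, 3.0, 4.0, 5.0),
            n=N_TREND,
            seed_base=0,
        )
        summ = summarise_sweep(tidy)
        for c, block in summ.groupby("collapse_C"):
            block = block.sort_values("peep")
            t = block["t_R_mean"].to_numpy()
            g = block["G_net_mean"].to_numpy()
            assert np.all(np.diff(t) < 0), f"C={c}: {t}"
            assert g[-1] > g[0], f"C={c}: {g}"
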