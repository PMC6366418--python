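"""Least-squares fitting: recovery, grid oracle, cascade contracts."""

import numpy as np
import pytest

from enzkin.errors import InsufficientDataError, UnidentifiableError
from enzkin.fitting import CASCADE_ORDER, fit_cascade, fit_model
from enzkin.mechanisms import Condition, KineticParameters, Mechanism
from enzkin.rates import VelocityObservation
from enzkin.selection import select_mechanism

from conftest import make_observations


@pytest.fixture
def comp_obs(b4_params):
    return make_observations(
        Mechanism.COMPETITIVE, b4_params,
        substrates=(0.25, 0.5, 1.0), inhibitors=(0.0, 50.0, 100.0, 200.0),
    )


class TestFitModel:
    def test_noiseless_exact_recovery(self, comp_obs, b4_params):
        fit = fit_model(comp_obs, Mechanism.COMPETITIVE)
        assert fit.converged
        assert fit.ssr < 1e-16
        assert fit.params.vmax == pytest.approx(b4_params.vmax, rel=1e-4)
        assert fit.params.km == pytest.approx(b4_params.km, rel=1e-4)
        assert fit.params.kic == pytest.approx(b4_params.kic, rel=1e-4)

    def test_ssr_beats_brute_force_grid(self, comp_obs):
        # 40^3 log-grid over (Vmax, Km, Kic) as an independent oracle
        v = np.array([o.v for o in comp_obs])
        S = np.array([o.cond.S for o in comp_obs])
        I = np.array([o.cond.I for o in comp_obs])
        vmax_g = np.geomspace(1.0, 100.0, 40)
        km_g = np.geomspace(0.05, 10.0, 40)
        kic_g = np.geomspace(1.0, 2000.0, 40)
        best = np.inf
        for vm in vmax_g:
            pred = (
                vm * S[None, None, :]
                / (km_g[:, None, None] * (1 + I[None, None, :] / kic_g[None, :, None])
                   + S[None, None, :])
            )
            ssr = np.sum((v - pred) ** 2, axis=-1).min()
            best = min(best, float(ssr))
        fit = fit_model(comp_obs, Mechanism.COMPETITIVE)
        assert fit.ssr <= best * 1.01

    def test_all_controls_unidentifiable(self, b4_params):
        obs = make_observations(
            Mechanism.COMPETITIVE, b4_params,
            substrates=(0.25, 0.5, 1.0), inhibitors=(0.0,),
        )
        with pytest.raises(UnidentifiableError):
            fit_model(obs, Mechanism.COMPETITIVE)

    def test_single_substrate_insufficient(self, b4_params):
        obs = make_observations(
            Mechanism.COMPETITIVE, b4_params,
            substrates=(0.5,), inhibitors=(0.0, 50.0, 100.0),
        )
        with pytest.raises(InsufficientDataError):
            fit_model(obs, Mechanism.COMPETITIVE)

    def test_too_few_observations(self):
        obs = [
            VelocityObservation(Condition(S=0.25), 1, 2.0, 0.0, 1.0),
            VelocityObservation(Condition(S=1.0), 1, 6.0, 0.0, 1.0),
        ]
        with pytest.raises(InsufficientDataError):
            fit_model(obs, Mechanism.NONE)

    @pytest.mark.parametrize(
        "mech, params",
        [
            (Mechanism.NONE, KineticParameters(12.0, 1.2)),
            (Mechanism.UNCOMPETITIVE, KineticParameters(12.0, 1.2, kiu=30.0)),
            (Mechanism.NONCOMPETITIVE, KineticParameters(12.0, 1.2, kic=40.0, kiu=40.0)),
            (Mechanism.MIXED, KineticParameters(12.0, 0.9, kic=60.0, kiu=15.0)),
        ],
    )
    def test_zero_noise_recovery_all_mechanisms(self, mech, params):
        obs = make_observations(
            mech, params,
            substrates=(0.25, 0.5, 1.0), inhibitors=(0.0, 10.0, 30.0, 100.0),
        )
        fit = fit_model(obs, mech)
        for name, truth_val in params.as_dict().items():
            if truth_val is None:
                continue
            got = fit.params.as_dict()[name]
            assert got == pytest.approx(truth_val, rel=1e-5), name

    def test_inhibitor_unit_rescaling_equivariance(self, comp_obs):
        fit_uM = fit_model(comp_obs, Mechanism.COMPETITIVE)
        obs_nM = [
            VelocityObservation(
                cond=Condition(S=o.cond.S, I=o.cond.I * 1e3),
                replicate=o.replicate, v=o.v, slope=o.slope, r_squared=o.r_squared,
            )
            for o in comp_obs
        ]
        fit_nM = fit_model(obs_nM, Mechanism.COMPETITIVE)
        assert fit_nM.params.kic == pytest.approx(fit_uM.params.kic * 1e3, rel=1e-9)
        assert fit_nM.params.vmax == pytest.approx(fit_uM.params.vmax, rel=1e-9)
        assert fit_nM.params.km == pytest.approx(fit_uM.params.km, rel=1e-9)


class TestFitCascade:
    def test_returns_five_in_cascade_order(self, comp_obs):
        fits = fit_cascade(comp_obs)
        assert tuple(f.mech for f in fits) == CASCADE_ORDER

    def test_ssr_monotone_along_nesting_chains(self, b4_plate):
        from enzkin.rates import extract_velocities

        obs = extract_velocities(b4_plate).observations
        fits = {f.mech: f for f in fit_cascade(obs)}
        tol = 1e-9
        for three in (Mechanism.COMPETITIVE, Mechanism.NONCOMPETITIVE,
                      Mechanism.UNCOMPETITIVE):
            assert fits[three].ssr <= fits[Mechanism.NONE].ssr + tol
            assert fits[Mechanism.MIXED].ssr <= fits[three].ssr + tol

    def test_individual_vs_mean_fits_can_disagree_near_boundary(self):
        # weak uncompetitive component on top of strong competitive binding:
        # averaging replicates before fitting can flip the selected mechanism
        truth = KineticParameters(12.0, 1.2, kic=132.0, kiu=3000.0)
        disagreements = 0
        for seed in range(50):
            obs = make_observations(
                Mechanism.MIXED, truth,
                substrates=(0.25, 0.5, 1.0),
                inhibitors=(0.0, 25.0, 50.0, 100.0, 200.0),
                replicates=3, noise_sd=0.08, seed=seed,
            )
            means = {}
            for o in obs:
                means.setdefault((o.cond.S, o.cond.I), []).append(o.v)
            mean_obs = [
                VelocityObservation(Condition(S=s, I=i), 1, float(np.mean(vs)), 0.0, 1.0)
                for (s, i), vs in means.items()
            ]
            chosen_ind = select_mechanism(fit_cascade(obs, seed=seed)).chosen
            chosen_mean = select_mechanism(fit_cascade(mean_obs, seed=seed)).chosen
            if chosen_ind is not chosen_mean:
                disagreements += 1
        assert disagreements >= 1
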