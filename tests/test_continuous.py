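import numpy as np
import pytest

import nbcascade as nb
from nbcascade.continuous import ContinuousParams


def strong_params(net, **kw):
    Jt = np.where(net.J == 1, 2.0, 0.0) + np.where(net.J == -5, -5.0, 0.0)
    S = np.array([1.0, 0.1, 0.1, 0.1, 1.0])
    return ContinuousParams(strengths=Jt, promoters=S, **kw)


@pytest.fixture(scope="module")
def dros_params():
    net = nb.drosophila_network(include_hb_to_cas=True, include_x=True)
    return net, strong_params(net)


class TestPromoterActivity:
    def test_no_regulators_gives_default_activity(self, dros_params):
        net, p = dros_params
        assert nb.promoter_activity(np.zeros(5), "Kr", p, 0.0) == p.promoters[1]

    def test_saturated_repressor_silences(self, dros_params):
        net, p = dros_params
        prot = np.zeros(5)
        prot[0] = 10.0   # hb far above K_M represses pdm at strength -5
        assert nb.promoter_activity(prot, "pdm", p, 0.0) == 0.0

    def test_hb_promoter_switches_off(self, dros_params):
        net, p = dros_params
        assert nb.promoter_activity(np.zeros(5), "hb", p, 5.0) > 0
        assert nb.promoter_activity(np.zeros(5), "hb", p, 15.0) == 0.0


class TestIntegrate:
    def test_deterministic_without_noise(self, dros_params):
        net, p = dros_params
        a = nb.integrate(p, params=p, seed=1)
        b = nb.integrate(p, params=p, seed=99)
        assert np.array_equal(a.protein, b.protein)

    def test_non_negative_concentrations(self, dros_params):
        net, p = dros_params
        traj = nb.integrate(p, params=p)
        assert (traj.protein >= 0).all() and (traj.mrna >= 0).all()

    def test_noise_reproducible_by_seed_and_law(self, dros_params):
        net, p = dros_params
        pn = p.with_(sigma=0.3, t_total=2.0)
        a = nb.integrate(pn, params=pn, seed=7, record_stride=1)
        b = nb.integrate(pn, params=pn, seed=7, record_stride=1)
        c = nb.integrate(pn, params=pn, seed=8, record_stride=1)
        assert np.array_equal(a.mrna, b.mrna)
        assert not np.array_equal(a.mrna, c.mrna)
        # Euler-Maruyama increment law: with a strong promoter the
        # zero-clamp is inactive and the first-step mRNA variance is
        # sigma^2 dt
        ps = pn.with_(promoters=np.array([1.0, 10.0, 0.1, 0.1, 1.0]))
        reps = [nb.integrate(ps, params=ps, seed=s, record_stride=1).mrna[1, 1]
                for s in range(300)]
        var = np.var(reps)
        expect = ps.sigma ** 2 * ps.dt
        assert 0.7 * expect < var < 1.4 * expect

    def test_dt_halving_convergence(self, dros_params):
        """Noise-free trajectories converge at first order in dt (the
        error roughly halves with the step)."""
        net, p = dros_params
        base = nb.integrate(p.with_(dt=0.02), params=p.with_(dt=0.02),
                            record_stride=50)
        half = nb.integrate(p.with_(dt=0.01), params=p.with_(dt=0.01),
                            record_stride=100)
        err = np.abs(base.protein - half.protein).max()
        quarter = nb.integrate(p.with_(dt=0.005), params=p.with_(dt=0.005),
                               record_stride=200)
        err2 = np.abs(half.protein - quarter.protein).max()
        # ~2% of the protein scale at dt=0.02, halving with dt
        assert err < 0.04 * p.promoters[0] / p.d_p
        assert 0.3 < err2 / err < 0.7

    def test_wild_type_cascade_reproduced(self, dros_params):
        net, p = dros_params
        assert nb.wt_success(net, p)

    def test_boolean_continuous_consistency(self, dros_params):
        """Strong regulation, no noise: the discretized phase order equals
        the Boolean model's WT sequence."""
        net, p = dros_params
        traj = nb.integrate(p, params=p)
        d = nb.discretize(traj, p.p_th)
        onsets = []
        for i in range(4):
            on = np.flatnonzero(d[:, i])
            assert on.size
            onsets.append(on[0])
        assert onsets == sorted(onsets)
        bool_traj = nb.simulate(net, nb.GenotypeSpec(), (0, 1, 1),
                                nb.InputSchedule(t_end=10, t_x=1))
        bool_onsets = [bool_traj.window(g)[0]
                       for g in ("hb", "Kr", "pdm", "cas")]
        assert bool_onsets == sorted(bool_onsets)


class TestDiscretize:
    def test_all_zero_is_all_off(self, dros_params):
        net, p = dros_params
        traj = nb.ContinuousTrajectory(
            t=np.arange(5.0), mrna=np.zeros((5, 5)), protein=np.zeros((5, 5)))
        assert not nb.discretize(traj, 0.2).any()

    def test_above_threshold_is_on_and_tie_is_off(self):
        prot = np.full((3, 5), 0.3)
        traj = nb.ContinuousTrajectory(t=np.arange(3.0),
                                       mrna=np.zeros((3, 5)), protein=prot)
        assert nb.discretize(traj, 0.2).all()
        assert not nb.discretize(traj, 0.3).any()   # exact tie maps to OFF

    def test_threshold_must_be_positive(self):
        traj = nb.ContinuousTrajectory(t=np.arange(2.0),
                                       mrna=np.zeros((2, 5)),
                                       protein=np.zeros((2, 5)))
        with pytest.raises(ValueError):
            nb.discretize(traj, 0.0)


class TestWtSuccess:
    def test_zero_parameters_fail(self):
        net = nb.SignNetwork(np.zeros((3, 5)))
        p = ContinuousParams(strengths=np.zeros((3, 5)),
                             promoters=np.zeros(5))
        assert not nb.wt_success(net, p)

    def test_missing_activation_with_tiny_default_fails(self):
        net = nb.minimum_network()
        Jt = np.where(net.J == 1, 2.0, 0.0) + np.where(net.J == -5, -5.0, 0.0)
        S = np.array([1.0, 0.1, 1e-4, 0.1, 1.0])   # S_pdm ~ 0, no Kr->pdm
        p = ContinuousParams(strengths=Jt, promoters=S)
        assert not nb.wt_success(net, p)
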