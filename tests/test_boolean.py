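import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nbcascade as nb
from nbcascade.boolean import BooleanState, initial_state
from tests.conftest import random_network

SCHED = nb.InputSchedule(t_end=10, t_x=4)
WT = nb.GenotypeSpec()


class TestStep:
    def test_hand_evaluated_update_on_reference_network(self):
        # hb and x ON: Kr sum = +1 (hb) +1 (x) = 2 > 0 -> ON;
        # pdm sum = -5 (hb) < 0 -> OFF; cas sum = -5 -5 = -10 < 0 -> OFF
        net = nb.drosophila_network(include_hb_to_cas=True, include_x=True)
        st0 = BooleanState(hb=1, Kr=0, pdm=0, cas=0, x=1)
        nxt = nb.step(st0, 0, net, (0, 0, 0), WT, SCHED)
        assert (nxt.Kr, nxt.pdm, nxt.cas) == (1, 0, 0)

    def test_zero_input_applies_default_states(self):
        empty = nb.SignNetwork(np.zeros((3, 5)))
        st0 = BooleanState(hb=0, Kr=1, pdm=1, cas=1)
        nxt = nb.step(st0, 5, empty, (1, 0, 1), WT, SCHED)
        assert (nxt.Kr, nxt.pdm, nxt.cas) == (1, 0, 1)

    def test_overexpression_clamp_wins_over_any_input(self, rng):
        geno = nb.GenotypeSpec("Kr", "oe")
        for _ in range(20):
            net = random_network(rng)
            st0 = BooleanState(hb=1, Kr=1, pdm=1, cas=1, x=1)
            assert nb.step(st0, 0, net, (0, 0, 0), geno, SCHED).Kr == 1


class TestSimulate:
    def test_wild_type_cascade_on_reference_network(self, dros):
        traj = nb.simulate(dros, WT, (0, 1, 1), nb.InputSchedule(t_end=10, t_x=1))
        seq = nb.compress(traj)
        # ordered phases: Hb alone, then Kr, then pdm, then cas (with
        # transient co-expression states in between)
        assert seq[0] == (1, 0, 0, 0)
        onsets = [traj.window(g)[0] for g in ("hb", "Kr", "pdm", "cas")]
        assert onsets == sorted(onsets)
        assert traj.window("cas")[1] == 10   # cas persists to the end

    def test_initial_state_is_hb_only(self):
        st0 = initial_state(WT, SCHED)
        assert (st0.hb, st0.Kr, st0.pdm, st0.cas) == (1, 0, 0, 0)
        assert st0.x == 1   # ON->OFF polarity starts high

    def test_hb_input_window_is_two_steps(self, dros):
        traj = nb.simulate(dros, WT, (0, 0, 0), SCHED)
        assert list(traj.gene("hb")) == [1, 1] + [0] * 9
        assert list(traj.gene("svp")) == [0, 1] + [0] * 9

    def test_loss_clamp_holds_entire_trajectory(self, rng):
        geno = nb.GenotypeSpec("hb", "loss")
        for _ in range(20):
            net = random_network(rng)
            traj = nb.simulate(net, geno, (1, 1, 1), SCHED)
            assert not traj.gene("hb").any()

    def test_determinism(self, dros):
        a = nb.simulate(dros, WT, (1, 0, 1), SCHED)
        b = nb.simulate(dros, WT, (1, 0, 1), SCHED)
        assert np.array_equal(a.states, b.states)

    def test_no_default_choice_rescues_every_mutant_without_x(self, dros_no_x):
        # the reconstructed network alone cannot satisfy all nine genotype
        # profiles for any default-state combination
        net = dros_no_x.with_x()
        assert nb.find_witness(net) is None


class TestRepressorDominance:
    @given(st.integers(min_value=0, max_value=3 ** 15 - 1),
           st.integers(min_value=0, max_value=7))
    @settings(max_examples=200, deadline=None)
    def test_active_strong_repressor_silences_target(self, code, s0):
        """With <= 4 activators at +1, one active -5 input forces OFF."""
        net = nb.SignNetwork.from_code(code)
        defaults = (s0 & 1, (s0 >> 1) & 1, (s0 >> 2) & 1)
        traj = nb.simulate(net, WT, defaults, SCHED)
        states = traj.states
        for t in range(len(states) - 1):
            regs = [states[t, 0], states[t, 1], states[t, 2], states[t, 3],
                    states[t, 5]]
            for i in range(3):
                row = net.J[i]
                if any(v == -5 and r for v, r in zip(row, regs)):
                    assert states[t + 1, 1 + i] == 0


class TestCompress:
    def test_constant_trajectory_compresses_to_one_state(self):
        traj = nb.BooleanTrajectory(np.tile([0, 1, 0, 0, 0, 0], (5, 1)))
        assert nb.compress(traj) == ((0, 1, 0, 0),)

    def test_idempotent(self, dros, rng):
        for _ in range(10):
            net = random_network(rng)
            traj = nb.simulate(net, WT, (1, 1, 0), SCHED)
            seq = nb.compress(traj)
            assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_tidy_frame_shape(self, dros):
        df = nb.simulate(dros, WT, (0, 0, 0), SCHED).to_frame()
        assert set(df.columns) == {"t", "gene", "state"}
        assert len(df) == 11 * 6
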