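import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nbcascade as nb
from nbcascade.network import N_NETWORKS_12, N_NETWORKS_15


class TestReferenceNetwork:
    def test_regulations_match_literature_reconstruction(self):
        net = nb.drosophila_network(include_hb_to_cas=True, include_x=False)
        assert net["Kr", "hb"] == 1
        assert net["pdm", "hb"] == -5
        assert net["cas", "hb"] == -5
        assert net["pdm", "Kr"] == 1
        assert net["cas", "Kr"] == -5
        assert net["Kr", "pdm"] == -5
        assert net["cas", "pdm"] == 1
        assert net["pdm", "cas"] == -5
        for g in ("Kr", "pdm", "cas"):
            assert net[g, g] == 0
        assert all(net[t, "x"] == 0 for t in ("Kr", "pdm", "cas"))

    def test_hb_to_cas_repression_is_optional(self):
        net = nb.drosophila_network(include_hb_to_cas=False, include_x=False)
        assert net["cas", "hb"] == 0

    def test_x_regulations(self):
        net = nb.drosophila_network(include_hb_to_cas=True, include_x=True)
        assert net["Kr", "x"] == 1
        assert net["cas", "x"] == -5
        assert net["pdm", "x"] == 0

    def test_minimum_network_drops_three_regulations(self):
        mini = nb.minimum_network()
        dros = nb.drosophila_network(include_hb_to_cas=True, include_x=True)
        assert mini["pdm", "Kr"] == 0
        assert mini["cas", "pdm"] == 0
        assert mini["cas", "hb"] == 0
        # everything else identical
        diff = (mini.J != dros.J).sum()
        assert diff == 3


class TestEncoding:
    def test_zero_code_is_empty_network(self):
        assert not nb.SignNetwork.from_code(0, include_x=False).J.any()

    def test_top_code_fills_every_slot_with_last_digit_value(self):
        net = nb.SignNetwork.from_code(N_NETWORKS_12 - 1, include_x=False)
        assert (net.J[:, :4] == -5).all()
        assert not net.J[:, 4].any()

    def test_code_range_validation(self):
        with pytest.raises(ValueError):
            nb.SignNetwork.from_code(N_NETWORKS_12, include_x=False)
        with pytest.raises(ValueError):
            nb.SignNetwork.from_code(-1)

    @given(st.integers(min_value=0, max_value=N_NETWORKS_15 - 1))
    @settings(max_examples=100, deadline=None)
    def test_decode_encode_roundtrip(self, code):
        net = nb.SignNetwork.from_code(code)
        assert net.code == code
        assert nb.SignNetwork.from_code(net.code) == net

    def test_12_and_15_slot_variants_interconvert(self):
        net12 = nb.drosophila_network(include_hb_to_cas=True, include_x=False)
        net15 = net12.with_x()
        assert net15.include_x and np.array_equal(net12.J, net15.J)
        assert net15.without_x() == net12


class TestSerialization:
    def test_json_roundtrip(self, dros):
        assert nb.SignNetwork.from_json(dros.to_json()) == dros

    def test_edge_list_roundtrip(self, dros):
        rows = dros.edge_list()
        assert ("hb", "Kr", 1) in rows
        assert nb.SignNetwork.from_edge_list(rows) == dros


class TestGenotypes:
    def test_exactly_nine_genotypes(self):
        names = [g.name for g in nb.GENOTYPES]
        assert names == ["wt", "hb-", "Kr-", "pdm-", "cas-",
                         "hb++", "Kr++", "pdm++", "cas++"]

    def test_name_roundtrip(self):
        for g in nb.GENOTYPES:
            assert nb.GenotypeSpec.from_name(g.name) == g

    def test_invalid_genotypes_rejected(self):
        with pytest.raises(ValueError):
            nb.GenotypeSpec("svp", "loss")
        with pytest.raises(ValueError):
            nb.GenotypeSpec("Kr", "banana")

    def test_clamp_values(self):
        assert nb.GenotypeSpec("Kr", "loss").clamp_value == 0
        assert nb.GenotypeSpec("Kr", "oe").clamp_value == 1
        assert nb.GenotypeSpec().clamp_value is None

    def test_eight_default_state_combinations(self):
        assert len(set(nb.default_states())) == 8


class TestInputSchedule:
    def test_svp_pulses_only_at_step_one(self):
        s = nb.InputSchedule(t_end=10, t_x=3)
        assert [s.svp_input(t) for t in range(5)] == [0, 1, 0, 0, 0]

    def test_x_switches_once(self):
        s = nb.InputSchedule(t_end=10, t_x=3)
        xs = [s.x_input(t) for t in range(6)]
        assert xs == [1, 1, 1, 0, 0, 0]
        flips = sum(a != b for a, b in zip(xs, xs[1:]))
        assert flips == 1

    def test_off_on_polarity_inverts(self):
        s = nb.InputSchedule(t_end=10, t_x=3, x_polarity="off_on")
        assert [s.x_input(t) for t in range(5)] == [0, 0, 0, 1, 1]

    def test_t_x_bounds(self):
        with pytest.raises(ValueError):
            nb.InputSchedule(t_end=10, t_x=0)
        with pytest.raises(ValueError):
            nb.InputSchedule(t_end=10, t_x=11)
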