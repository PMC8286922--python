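"""Random-graph construction, synaptic transmission, and STDP."""

import numpy as np
import pytest

from bgloop.connectivity import (
    NetworkGraph,
    PopulationSpec,
    Projection,
    ProjectionSpec,
    StdpProfile,
    build_network,
    corticostriatal_gain,
    load_network_defaults,
    network_from_config,
    stdp_update,
    synaptic_input,
)
from bgloop.simulate import SpikeRecord


def tiny_specs(params, sizes=None):
    sizes = sizes or {"CTX_RS": 20, "D1_MSN": 10, "D2_MSN": 10}
    return [PopulationSpec(name=n, size=s, neuron_params=params[n])
            for n, s in sizes.items()]


PROFILE = StdpProfile(
    name="test", potentiation_amplitude=1.0, depression_amplitude=0.8,
    potentiation_tau=20.0, depression_tau=25.0, weight_bounds=(0.0, 100.0),
)


def plastic_projection(p=1.0):
    return ProjectionSpec(source="CTX_RS", target="D1_MSN", sign="excitatory",
                          connection_probability=p, weight_mean=50.0,
                          delay=2.0, plastic=True, stdp_profile="test")


class TestBuildNetwork:
    def test_zero_probability_means_no_edges(self, params):
        spec = ProjectionSpec("CTX_RS", "D1_MSN", "excitatory", 0.0, 10.0)
        g = build_network(tiny_specs(params), [spec], seed=1)
        assert len(g.projections["CTX_RS->D1_MSN"]) == 0

    def test_full_probability_edge_counts(self, params):
        across = ProjectionSpec("CTX_RS", "D1_MSN", "excitatory", 1.0, 10.0)
        within = ProjectionSpec("CTX_RS", "CTX_RS", "excitatory", 1.0, 10.0)
        g = build_network(tiny_specs(params), [across, within], seed=1)
        assert len(g.projections["CTX_RS->D1_MSN"]) == 20 * 10
        # no self-connections within a population
        assert len(g.projections["CTX_RS->CTX_RS"]) == 20 * 19

    def test_determinism(self, params):
        spec = ProjectionSpec("CTX_RS", "D1_MSN", "excitatory", 0.3, 10.0,
                              weight_spread=2.0, delay=2.0, delay_jitter=0.5)
        g1 = build_network(tiny_specs(params), [spec], seed=99)
        g2 = build_network(tiny_specs(params), [spec], seed=99)
        p1, p2 = g1.projections["CTX_RS->D1_MSN"], g2.projections["CTX_RS->D1_MSN"]
        assert np.array_equal(p1.src, p2.src)
        assert np.array_equal(p1.weight, p2.weight)
        assert np.array_equal(p1.delay, p2.delay)

    def test_sign_and_delay_invariants_on_defaults(self, params):
        g = network_from_config(load_network_defaults(), params, seed=5)
        for proj in g.projections.values():
            proj.check_invariants()
            if proj.spec.sign == "inhibitory":
                assert np.all(proj.weight <= 0)
            else:
                assert np.all(proj.weight >= 0)
            assert np.all(proj.delay > 0)

    def test_plastic_flags_follow_the_three_cortical_classes(self, params):
        """Plasticity lives exactly on RS->RS, RS->FS and RS->D1."""
        g = network_from_config(load_network_defaults(), params, seed=5)
        plastic = {name for name, p in g.projections.items() if p.spec.plastic}
        assert plastic == {"CTX_RS->CTX_RS", "CTX_RS->CTX_FS", "CTX_RS->D1_MSN"}

    def test_unknown_population_rejected(self, params):
        bad = ProjectionSpec("CTX_RS", "GPe", "inhibitory", 0.5, 10.0)
        with pytest.raises(KeyError):
            build_network(tiny_specs(params), [bad], seed=1)

    def test_prune_reduction_scales_total_strength(self, params):
        spec = ProjectionSpec("CTX_RS", "D1_MSN", "excitatory", 1.0, 10.0)
        g = build_network(tiny_specs(params), [spec], seed=3)
        before = g.projections["CTX_RS->D1_MSN"].weight.sum()
        g.scale_projection("CTX_RS->D1_MSN", 0.3, mode="prune")
        after = g.projections["CTX_RS->D1_MSN"].weight.sum()
        assert 0.15 * before < after < 0.45 * before


class TestSynapticInput:
    def make_single_edge_graph(self, params):
        g = build_network(tiny_specs(params),
                          [ProjectionSpec("CTX_RS", "D1_MSN", "excitatory",
                                          0.0, 0.0, delay=3.0)], seed=1)
        proj = g.projections["CTX_RS->D1_MSN"]
        proj.src = np.array([2])
        proj.dst = np.array([5])
        proj.weight = np.array([40.0])
        proj.delay = np.array([3.0])
        return g

    def record(self, g, spikes):
        return SpikeRecord(g.population_sizes, spikes, duration=100.0)

    def test_no_spikes_gives_zero_current(self, params):
        g = self.make_single_edge_graph(params)
        out = synaptic_input(g, self.record(g, {}), phi=0.5, t=10.0)
        assert all(np.all(v == 0.0) for v in out.values())

    def test_delta_pulse_arrives_at_spike_plus_delay(self, params):
        g = self.make_single_edge_graph(params)
        rec = self.record(g, {"CTX_RS": (np.array([2]), np.array([7.0]))})
        hit = synaptic_input(g, rec, phi=0.5, t=10.0)
        assert hit["D1_MSN"][5] == pytest.approx(40.0)
        assert np.count_nonzero(hit["D1_MSN"]) == 1
        miss = synaptic_input(g, rec, phi=0.5, t=10.5)
        assert np.all(miss["D1_MSN"] == 0.0)

    def test_history_start_violation(self, params):
        g = self.make_single_edge_graph(params)
        rec = SpikeRecord(g.population_sizes, {}, duration=100.0, t_start=50.0)
        with pytest.raises(ValueError):
            synaptic_input(g, rec, phi=0.5, t=10.0)

    def test_dopamine_scales_corticostriatal_efficacy(self, params):
        """The same cortical spike pattern delivers more current to D1 and
        less to D2 as phi rises (recomputed by brute force at both levels)."""
        specs = tiny_specs(params)
        projs = [
            ProjectionSpec("CTX_RS", "D1_MSN", "excitatory", 0.5, 30.0,
                           delay=2.0, da_gain=1.6),
            ProjectionSpec("CTX_RS", "D2_MSN", "excitatory", 0.5, 30.0,
                           delay=2.0, da_gain=-1.6),
        ]
        g = build_network(specs, projs, seed=11)
        rec = SpikeRecord(g.population_sizes,
                          {"CTX_RS": (np.arange(20), np.full(20, 5.0))},
                          duration=50.0)
        lo = synaptic_input(g, rec, phi=0.5, t=7.0)
        hi = synaptic_input(g, rec, phi=1.0, t=7.0)
        assert hi["D1_MSN"].sum() > lo["D1_MSN"].sum() > 0
        assert hi["D2_MSN"].sum() < lo["D2_MSN"].sum()

    def test_gain_is_neutral_at_tonic_baseline(self):
        assert corticostriatal_gain(1.6, 0.5) == 1.0
        assert corticostriatal_gain(-1.6, 0.5) == 1.0
        assert corticostriatal_gain(1.6, 1.0) == pytest.approx(1.8)
        assert corticostriatal_gain(-1.6, 1.0) == pytest.approx(0.2)


def brute_force_stdp(proj, profile, pre, post):
    """O(n^2) pair-sum oracle for the additive all-pairs rule."""
    dw = np.zeros(len(proj))
    for e in range(len(proj)):
        for ta in pre[proj.src[e]]:
            for tb in post[proj.dst[e]]:
                dt = tb - ta
                if dt > 0:
                    dw[e] += profile.potentiation_amplitude * np.exp(-dt / profile.potentiation_tau)
                elif dt < 0:
                    dw[e] -= profile.depression_amplitude * np.exp(dt / profile.depression_tau)
    return dw


class TestStdp:
    def build(self, params, p=1.0):
        g = build_network(tiny_specs(params), [plastic_projection(p)], seed=2,
                          stdp_profiles={"test": PROFILE})
        return g, g.projections["CTX_RS->D1_MSN"]

    def empty_trains(self, n):
        return [np.empty(0)] * n

    def test_no_spikes_leaves_weights_unchanged(self, params):
        g, proj = self.build(params)
        before = proj.weight.copy()
        stdp_update(g, PROFILE, self.empty_trains(20), self.empty_trains(10),
                    "CTX_RS->D1_MSN")
        assert np.array_equal(proj.weight, before)

    def test_pre_before_post_potentiates(self, params):
        g, proj = self.build(params)
        e = 0
        pre = self.empty_trains(20)
        post = self.empty_trains(10)
        pre[proj.src[e]] = np.array([10.0])
        post[proj.dst[e]] = np.array([15.0])
        before = proj.weight[e]
        stdp_update(g, PROFILE, pre, post, "CTX_RS->D1_MSN")
        assert proj.weight[e] > before

    def test_simultaneous_spikes_no_update(self, params):
        g, proj = self.build(params)
        pre = self.empty_trains(20)
        post = self.empty_trains(10)
        pre[proj.src[0]] = np.array([10.0])
        post[proj.dst[0]] = np.array([10.0])
        before = proj.weight.copy()
        stdp_update(g, PROFILE, pre, post, "CTX_RS->D1_MSN")
        assert np.array_equal(proj.weight, before)

    def test_matches_brute_force_pair_sum(self, params, rng):
        """Batch update equals the O(n^2) pair-sum over Poisson trains."""
        g, proj = self.build(params, p=0.4)
        pre = [np.sort(rng.uniform(0, 300.0, rng.poisson(6))) for _ in range(20)]
        post = [np.sort(rng.uniform(0, 300.0, rng.poisson(6))) for _ in range(10)]
        wide = StdpProfile("test", 0.5, 0.4, 15.0, 30.0, (-1e9, 1e9))
        expected = proj.weight + brute_force_stdp(proj, wide, pre, post)
        stdp_update(g, wide, pre, post, "CTX_RS->D1_MSN")
        np.testing.assert_allclose(proj.weight, expected, rtol=1e-9, atol=1e-9)

    def test_weights_stay_within_bounds(self, params, rng):
        g, proj = self.build(params, p=0.4)
        pre = [np.sort(rng.uniform(0, 500.0, 30)) for _ in range(20)]
        post = [np.sort(rng.uniform(0, 500.0, 30)) for _ in range(10)]
        stdp_update(g, PROFILE, pre, post, "CTX_RS->D1_MSN")
        assert proj.weight.min() >= PROFILE.weight_bounds[0]
        assert proj.weight.max() <= PROFILE.weight_bounds[1]

    def test_non_plastic_projection_rejected(self, params):
        spec = ProjectionSpec("CTX_RS", "D1_MSN", "excitatory", 0.5, 10.0)
        g = build_network(tiny_specs(params), [spec], seed=2)
        with pytest.raises(ValueError, match="not plastic"):
            stdp_update(g, PROFILE, self.empty_trains(20), self.empty_trains(10),
                        "CTX_RS->D1_MSN")

    def test_rewiring_prunes_and_logs(self, params, rng):
        profile = StdpProfile("test", 0.0, 5.0, 20.0, 20.0, (0.0, 100.0),
                              allow_rewiring=True, rewire_probability=1.0,
                              min_positive_weight=1.0)
        g, proj = self.build(params)
        n_before = len(proj)
        # strong anti-causal pairing drives every active edge to the 0 bound
        pre = [np.array([t + 5.0 for t in range(0, 500, 10)]) for _ in range(20)]
        post = [np.array([float(t) for t in range(0, 500, 10)]) for _ in range(10)]
        stdp_update(g, profile, pre, post, "CTX_RS->D1_MSN", t_now=500.0,
                    rng=rng)
        actions = {a for _, a, _, _, _ in g.plasticity_log}
        assert "prune" in actions
        assert "form" in actions
        # pruned edges are gone; newly formed ones start at the minimum weight
        assert len(proj) <= n_before
        assert np.all(proj.weight[proj.weight > 0] >= 1.0)
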