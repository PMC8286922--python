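"""Random-graph wiring of the circuit, synaptic transmission, and STDP.

The network follows the canonical basal-ganglia motif: a posterior cortex
(regular-spiking excitatory + fast-spiking inhibitory populations, 4:1),
striatal D1-/D2-MSN populations, GPe, GPi, STN and thalamocortical relay
cells, wired as a directed random graph (each pre/post pair connected
independently with a per-projection probability).  Pathways:

* direct:      CTX -> D1-MSN -| GPi -| TC
* indirect:    CTX -> D2-MSN -| GPe -| STN -> GPi -| TC
* hyperdirect: CTX -> STN -> GPi -| TC

Synapses are delta-pulse current injections: a presynaptic spike at time t
adds a current pulse of the edge weight (pA, lasting one integration step)
onto the target at t + delay.  Dopamine scales the efficacy of the
cortico-striatal projections at delivery time: the gain is
``max(0, 1 + da_gain * (phi - 0.5))`` so that the tonic baseline phi = 0.5
is neutral, a dopamine surge boosts cortex->D1 (da_gain > 0) and depresses
cortex->D2 (da_gain < 0), and dopamine depletion does the opposite.

Plasticity: pair-based additive STDP (all-pairs) on the three plastic
connection classes (intra-cortical RS->RS, cortical RS->FS, and
cortico-striatal RS->D1), with distinct profiles for the intra-cortical and
cortico-striatal synapses, hard weight bounds against runaway potentiation,
and optional structural rewiring: an edge whose weight decays to 0 is pruned
and, with a small probability, replaced by a fresh edge between a uniformly
chosen unconnected pair of the same projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .neurons import NeuronParams

__all__ = [
    "PopulationSpec",
    "ProjectionSpec",
    "StdpProfile",
    "Projection",
    "NetworkGraph",
    "build_network",
    "synaptic_input",
    "stdp_update",
    "corticostriatal_gain",
    "load_network_defaults",
]

POPULATION_ORDER = ("CTX_RS", "CTX_FS", "D1_MSN", "D2_MSN", "GPe", "GPi", "STN", "TC")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    neuron_params: NeuronParams
    background_rate: float = 0.0    # Hz, per-neuron Poisson drive
    background_weight: float = 0.0  # pA pulse per background event
    bias_spread: float = 0.0        # pA std of per-neuron intrinsic-drive jitter

    def __post_init__(self) -> None:
        if self.name not in POPULATION_ORDER:
            raise ValueError(f"unknown population name {self.name!r}")
        if self.size <= 0:
            raise ValueError("population size must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass(frozen=True)
class StdpProfile:
    name: str
    potentiation_amplitude: float   # pA per causal pair at Dt -> 0+
    depression_amplitude: float
    potentiation_tau: float         # ms
    depression_tau: float           # ms
    weight_bounds: tuple[float, float]
    allow_rewiring: bool = False
    rewire_probability: float = 0.05   # per pruned edge per update epoch
    min_positive_weight: float = 1.0   # pA, initial weight of a rewired edge

    def __post_init__(self) -> None:
        if self.potentiation_tau <= 0 or self.depression_tau <= 0:
            raise ValueError("STDP time constants must be > 0")
        if self.weight_bounds[0] > self.weight_bounds[1]:
            raise ValueError("weight_bounds must be (min, max) with min <= max")


@dataclass(frozen=True)
class ProjectionSpec:
    source: str
    target: str
    sign: str                      # "excitatory" | "inhibitory"
    connection_probability: float
    weight_mean: float             # magnitude, pA
    weight_spread: float = 0.0     # stdev of the initial magnitude
    delay: float = 1.0             # ms
    delay_jitter: float = 0.0      # half-width of uniform per-edge jitter, ms
    plastic: bool = False
    stdp_profile: str | None = None
    da_gain: float = 0.0           # dopamine sensitivity of this projection

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"bad sign {self.sign!r}")
        if not 0.0 <= self.connection_probability <= 1.0:
            raise ValueError("connection_probability must lie in [0, 1]")
        if self.weight_mean < 0:
            raise ValueError("weight_mean is a magnitude; sign comes from `sign`")
        if self.delay - self.delay_jitter <= 0:
            raise ValueError("delays must stay > 0 (conduction takes time)")
        if self.plastic and self.stdp_profile is None:
            raise ValueError("plastic projections need an stdp_profile")

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class Projection:
    spec: ProjectionSpec
    src: np.ndarray      # local presynaptic indices
    dst: np.ndarray      # local postsynaptic indices
    weight: np.ndarray   # signed, pA
    delay: np.ndarray    # ms, per edge

    def __len__(self) -> int:
        return self.src.size

    def check_invariants(self) -> None:
        if self.spec.sign == "excitatory" and np.any(self.weight < 0):
            raise AssertionError(f"negative weight on excitatory {self.spec.name}")
        if self.spec.sign == "inhibitory" and np.any(self.weight > 0):
            raise AssertionError(f"positive weight on inhibitory {self.spec.name}")
        if np.any(self.delay <= 0):
            raise AssertionError(f"non-positive delay on {self.spec.name}")


@dataclass
class NetworkGraph:
    populations: list[PopulationSpec]
    projections: dict[str, Projection]
    stdp_profiles: dict[str, StdpProfile]
    rng_seed: int
    plasticity_log: list[tuple[float, str, str, int, int]] = field(default_factory=list)
    bias_jitter: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def population_sizes(self) -> dict[str, int]:
        return {p.name: p.size for p in self.populations}

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"unknown population {name!r}")

    def scale_projection(self, name: str, factor: float, mode: str = "prune",
                         rng: np.random.Generator | None = None) -> None:
        """Reduce a projection's total strength by ``factor`` (e.g. GPi->TC).

        ``mode='prune'`` removes each edge with probability 1 - factor while
        the survivors keep full strength (synaptic loss: some strengths drop
        to zero), so the expected total input scales by ``factor`` but its
        pulse statistics stay coarse.  ``mode='uniform'`` multiplies every
        weight instead.
        """
        proj = self.projections[name]
        if mode == "uniform":
            proj.weight *= factor
        elif mode == "prune":
            rng = rng or np.random.default_rng(self.rng_seed + 7)
            keep = rng.random(len(proj)) < factor
            proj.src = proj.src[keep]
            proj.dst = proj.dst[keep]
            proj.weight = proj.weight[keep]
            proj.delay = proj.delay[keep]
        else:
            raise ValueError(f"unknown reduction mode {mode!r}")

    def total_edges(self) -> int:
        return sum(len(p) for p in self.projections.values())

    def to_edge_list(self, path: str) -> None:
        """Write the wiring as delimited text (one header line)."""
        with open(path, "w") as fh:
            fh.write("source_pop\tsource_id\ttarget_pop\ttarget_id\tweight\tdelay_ms\n")
            for proj in self.projections.values():
                s, t = proj.spec.source, proj.spec.target
                for i in range(len(proj)):
                    fh.write(f"{s}\t{proj.src[i]}\t{t}\t{proj.dst[i]}\t"
                             f"{proj.weight[i]:.6g}\t{proj.delay[i]:.6g}\n")


def corticostriatal_gain(da_gain: float, phi: float) -> float:
    """Dopamine-dependent efficacy multiplier; neutral at phi = 0.5."""
    return max(0.0, 1.0 + da_gain * (phi - 0.5))


def build_network(
    specs: Sequence[PopulationSpec],
    projections: Sequence[ProjectionSpec],
    seed: int,
    stdp_profiles: Mapping[str, StdpProfile] | None = None,
) -> NetworkGraph:
    """Sample the random graph: each (pre, post) pair is connected
    independently with the projection's probability; self-connections are
    excluded within a population; weights are drawn from a truncated normal
    around the projection's mean magnitude.  Deterministic given ``seed``."""
    sizes = {p.name: p.size for p in specs}
    rng = np.random.default_rng(seed)
    # per-neuron intrinsic-drive jitter: real pacemaker nuclei span a range of
    # intrinsic rates, which keeps the population spectrum free of an
    # artificial line at one common firing frequency
    bias_jitter = {
        p.name: (rng.normal(0.0, p.bias_spread, p.size) if p.bias_spread > 0
                 else np.zeros(p.size))
        for p in specs
    }
    built: dict[str, Projection] = {}
    profiles = dict(stdp_profiles or {})
    for spec in projections:
        if spec.source not in sizes:
            raise KeyError(f"projection references unknown population {spec.source!r}")
        if spec.target not in sizes:
            raise KeyError(f"projection references unknown population {spec.target!r}")
        if spec.plastic and spec.stdp_profile not in profiles:
            raise KeyError(f"unknown stdp_profile {spec.stdp_profile!r} for {spec.name}")
        m, n = sizes[spec.source], sizes[spec.target]
        mask = rng.random((m, n)) < spec.connection_probability
        if spec.source == spec.target:
            np.fill_diagonal(mask, False)
        src, dst = np.nonzero(mask)
        mag = rng.normal(spec.weight_mean, spec.weight_spread, src.size)
        mag = np.clip(mag, 0.0, None)
        weight = mag if spec.sign == "excitatory" else -mag
        if spec.delay_jitter > 0:
            delay = rng.uniform(spec.delay - spec.delay_jitter,
                                spec.delay + spec.delay_jitter, src.size)
        else:
            delay = np.full(src.size, spec.delay)
        proj = Projection(spec=spec, src=src.astype(np.int64), dst=dst.astype(np.int64),
                          weight=weight.astype(float), delay=delay.astype(float))
        proj.check_invariants()
        built[spec.name] = proj
    graph = NetworkGraph(populations=list(specs), projections=built,
                         stdp_profiles=profiles, rng_seed=int(seed))
    graph.bias_jitter = bias_jitter
    return graph


def synaptic_input(
    graph: NetworkGraph,
    spike_history,
    phi: float,
    t: float,
    dt_tolerance: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Per-neuron synaptic current (pA) at time t by direct delayed summation.

    A presynaptic spike at time ts on an edge with delay d contributes its
    weight to the target exactly at t = ts + d.  This is the reference
    semantics; the simulation loop implements the same delivery with ring
    buffers.  Cortico-striatal contributions are scaled by the dopamine gain.
    """
    if t < spike_history.t_start:
        raise ValueError(
            f"t={t} precedes the spike history start {spike_history.t_start}"
        )
    out = {p.name: np.zeros(p.size) for p in graph.populations}
    for proj in graph.projections.values():
        spec = proj.spec
        ids, times = spike_history.spikes_of(spec.source)
        if times.size == 0 or len(proj) == 0:
            continue
        gain = corticostriatal_gain(spec.da_gain, phi) if spec.da_gain != 0.0 else 1.0
        tgt = out[spec.target]
        # arrivals: spike time + edge delay == t
        for e in range(len(proj)):
            pre = proj.src[e]
            ts = times[ids == pre]
            if ts.size == 0:
                continue
            hits = np.abs(ts + proj.delay[e] - t) <= dt_tolerance
            if np.any(hits):
                tgt[proj.dst[e]] += gain * proj.weight[e] * int(hits.sum())
    return out


# ---------------------------------------------------------------------------
# spike-timing-dependent plasticity
# ---------------------------------------------------------------------------

def _pairwise_stdp_sums(
    proj: Projection,
    profile: StdpProfile,
    pre_spikes: Sequence[np.ndarray],
    post_spikes: Sequence[np.ndarray],
) -> np.ndarray:
    """All-pairs additive STDP increment per edge, via time-ordered traces.

    Equivalent to the brute-force double sum over spike pairs:
    +A_p * exp(-Dt/tau_p) for each causal pair (Dt = t_post - t_pre > 0),
    -A_d * exp(-|Dt|/tau_d) for each anti-causal pair; simultaneous spikes
    (Dt == 0) contribute nothing.
    """
    n_pre = max(len(pre_spikes), int(proj.src.max()) + 1 if len(proj) else 0)
    n_post = max(len(post_spikes), int(proj.dst.max()) + 1 if len(proj) else 0)

    # CSR views of the edges by source and by target
    order_out = np.argsort(proj.src, kind="stable")
    out_ptr = np.searchsorted(proj.src[order_out], np.arange(n_pre + 1))
    order_in = np.argsort(proj.dst, kind="stable")
    in_ptr = np.searchsorted(proj.dst[order_in], np.arange(n_post + 1))

    events: list[tuple[float, int, int]] = []  # (time, kind 0=pre/1=post, neuron)
    for i, ts in enumerate(pre_spikes):
        for tt in np.asarray(ts, dtype=float):
            events.append((tt, 0, i))
    for j, ts in enumerate(post_spikes):
        for tt in np.asarray(ts, dtype=float):
            events.append((tt, 1, j))
    events.sort(key=lambda e: e[0])

    trace_pre = np.zeros(n_pre)
    trace_post = np.zeros(n_post)
    t_last_pre = np.zeros(n_pre)
    t_last_post = np.zeros(n_post)
    dw = np.zeros(len(proj))

    k = 0
    while k < len(events):
        t_now = events[k][0]
        group = []
        while k < len(events) and events[k][0] == t_now:
            group.append(events[k])
            k += 1
        # apply weight changes using traces that exclude this instant
        for _, kind, n_id in group:
            if kind == 1:  # post spike: potentiate in-edges by pre traces
                lo, hi = in_ptr[n_id], in_ptr[n_id + 1]
                e_idx = order_in[lo:hi]
                if e_idx.size:
                    srcs = proj.src[e_idx]
                    tr = trace_pre[srcs] * np.exp(-(t_now - t_last_pre[srcs]) / profile.potentiation_tau)
                    dw[e_idx] += profile.potentiation_amplitude * tr
            else:          # pre spike: depress out-edges by post traces
                lo, hi = out_ptr[n_id], out_ptr[n_id + 1]
                e_idx = order_out[lo:hi]
                if e_idx.size:
                    dsts = proj.dst[e_idx]
                    tr = trace_post[dsts] * np.exp(-(t_now - t_last_post[dsts]) / profile.depression_tau)
                    dw[e_idx] -= profile.depression_amplitude * tr
        # then fold this instant's spikes into the traces
        for _, kind, n_id in group:
            if kind == 0:
                trace_pre[n_id] = trace_pre[n_id] * np.exp(-(t_now - t_last_pre[n_id]) / profile.potentiation_tau) + 1.0
                t_last_pre[n_id] = t_now
            else:
                trace_post[n_id] = trace_post[n_id] * np.exp(-(t_now - t_last_post[n_id]) / profile.depression_tau) + 1.0
                t_last_post[n_id] = t_now
    return dw


def stdp_update(
    graph: NetworkGraph,
    profile: StdpProfile,
    pre_spikes: Sequence[np.ndarray],
    post_spikes: Sequence[np.ndarray],
    projection: str,
    t_now: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one batch of pair-based additive STDP to a plastic projection.

    ``pre_spikes``/``post_spikes`` are per-neuron spike-time arrays (local
    indices).  Weight changes are accumulated over all pairs, then clipped to
    the profile's bounds.  With ``allow_rewiring``, edges whose weight hits
    exactly the zero bound are pruned and occasionally replaced by a fresh
    edge between an unconnected pair.  Returns the updated weight array.
    """
    if projection not in graph.projections:
        raise KeyError(f"unknown projection {projection!r}")
    proj = graph.projections[projection]
    if not proj.spec.plastic:
        raise ValueError(f"projection {projection!r} is not plastic")
    if len(proj) == 0:
        return proj.weight
    dw = _pairwise_stdp_sums(proj, profile, pre_spikes, post_spikes)
    w_min, w_max = profile.weight_bounds
    proj.weight = np.clip(proj.weight + dw, w_min, w_max)

    if profile.allow_rewiring:
        rng = rng or np.random.default_rng(graph.rng_seed)
        dead = np.nonzero(proj.weight == 0.0)[0]
        if dead.size:
            keep = np.ones(len(proj), dtype=bool)
            keep[dead] = False
            n_src = graph.population(proj.spec.source).size
            n_tgt = graph.population(proj.spec.target).size
            existing = set(zip(proj.src[keep].tolist(), proj.dst[keep].tolist()))
            new_edges = []
            for e in dead:
                graph.plasticity_log.append(
                    (t_now, "prune", projection, int(proj.src[e]), int(proj.dst[e]))
                )
                if rng.random() < profile.rewire_probability:
                    for _ in range(20):  # rejection-sample an unconnected pair
                        s = int(rng.integers(n_src))
                        d = int(rng.integers(n_tgt))
                        if proj.spec.source == proj.spec.target and s == d:
                            continue
                        if (s, d) not in existing:
                            existing.add((s, d))
                            new_edges.append((s, d))
                            graph.plasticity_log.append((t_now, "form", projection, s, d))
                            break
            src = proj.src[keep]
            dst = proj.dst[keep]
            wts = proj.weight[keep]
            dls = proj.delay[keep]
            if new_edges:
                ns = np.array([e[0] for e in new_edges], dtype=np.int64)
                nd = np.array([e[1] for e in new_edges], dtype=np.int64)
                sign = 1.0 if proj.spec.sign == "excitatory" else -1.0
                nw = np.full(len(new_edges), sign * profile.min_positive_weight)
                ndl = np.full(len(new_edges), proj.spec.delay)
                src = np.concatenate([src, ns])
                dst = np.concatenate([dst, nd])
                wts = np.concatenate([wts, nw])
                dls = np.concatenate([dls, ndl])
            proj.src, proj.dst, proj.weight, proj.delay = src, dst, wts, dls
    proj.check_invariants()
    return proj.weight


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

def load_network_defaults(path: str | None = None) -> dict:
    """Raw network configuration table (sizes, probabilities, weights,
    delays, STDP profiles, background drive); packaged defaults if no path."""
    import yaml

    if path is None:
        from importlib.resources import files
        text = (files("bgloop") / "data" / "network_defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def network_from_config(
    config: dict,
    neuron_params: Mapping[str, NeuronParams],
    seed: int,
) -> NetworkGraph:
    """Instantiate the random graph from a configuration table."""
    specs = []
    for name in POPULATION_ORDER:
        entry = config["populations"][name]
        specs.append(PopulationSpec(
            name=name, size=int(entry["size"]),
            neuron_params=neuron_params[_cell_type_of(name)],
            background_rate=float(entry.get("background_rate", 0.0)),
            background_weight=float(entry.get("background_weight", 0.0)),
            bias_spread=float(entry.get("bias_spread", 0.0)),
        ))
    profiles = {}
    for pname, e in config.get("stdp_profiles", {}).items():
        profiles[pname] = StdpProfile(
            name=pname,
            potentiation_amplitude=float(e["potentiation_amplitude"]),
            depression_amplitude=float(e["depression_amplitude"]),
            potentiation_tau=float(e["potentiation_tau"]),
            depression_tau=float(e["depression_tau"]),
            weight_bounds=(float(e["weight_bounds"][0]), float(e["weight_bounds"][1])),
            allow_rewiring=bool(e.get("allow_rewiring", False)),
            rewire_probability=float(e.get("rewire_probability", 0.05)),
            min_positive_weight=float(e.get("min_positive_weight", 1.0)),
        )
    projections = []
    for e in config["projections"]:
        projections.append(ProjectionSpec(
            source=e["source"], target=e["target"], sign=e["sign"],
            connection_probability=float(e["p"]),
            weight_mean=float(e["weight_mean"]),
            weight_spread=float(e.get("weight_spread", 0.0)),
            delay=float(e.get("delay", 1.0)),
            delay_jitter=float(e.get("delay_jitter", 0.0)),
            plastic=bool(e.get("plastic", False)),
            stdp_profile=e.get("stdp_profile"),
            da_gain=float(e.get("da_gain", 0.0)),
        ))
    return build_network(specs, projections, seed, stdp_profiles=profiles)


def _cell_type_of(population: str) -> str:
    return population  # population names coincide with cell types
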