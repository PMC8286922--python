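"""Network integration loop: forward Euler over all populations with delayed
synaptic pulses, Poisson background drive, the external cortical stimulus,
dopamine-modulated cortico-striatal gain, and batched STDP.

The loop is fully vectorised over neurons.  Synaptic delivery uses ring
buffers: a spike of neuron i at step s adds, for every outgoing edge, the
edge weight into the buffer slot of step s + delay.  Projections whose
efficacy is dopamine-modulated accumulate into separate buffer channels so
the gain can be applied with the instantaneous phi(t) at delivery time.

STDP is applied in batches every ``stdp_update_interval`` (default 1 s)
using the spikes since the previous batch; for the additive all-pairs rule
this equals the online update up to the order in which clipping is applied
(documented approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectivity import NetworkGraph, corticostriatal_gain
from .dopamine import DopamineSchedule, phi_at
from .neurons import V_FLOOR, NeuronParams

__all__ = [
    "SimulationConfig",
    "StimulusSpec",
    "SpikeRecord",
    "run_simulation",
    "poisson_background",
]


@dataclass(frozen=True)
class StimulusSpec:
    """External cortical step input (constant current during a window).

    ``target_scales`` lets the step differ per population (the fast-spiking
    interneurons are far more excitable per pA, so they receive a smaller
    share of the same sensory drive).
    """

    amplitude: float = 0.0                 # pA
    window: tuple[float, float] = (0.0, 0.0)   # ms
    targets: tuple[str, ...] = ("CTX_RS", "CTX_FS")
    target_scales: tuple[float, ...] = (1.0, 0.45)
    #: per-neuron amplitude heterogeneity (fractional half-width of a uniform
    #: spread): a sensory volley drives individual cells unequally, which
    #: keeps the activated cortex from phase-locking its adaptation cycles
    amplitude_jitter: float = 0.8


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.5                        # ms
    duration: float = 600_000.0            # ms (10 min)
    record_window: tuple[float, float] | None = None  # default: final 7 s
    stdp_update_interval: float = 1000.0   # ms
    seed: int = 0
    stimulus: StimulusSpec = StimulusSpec()
    stdp_enabled: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        rw = self.record_window
        if rw is None:
            rw = (max(0.0, self.duration - 7000.0), self.duration)
            object.__setattr__(self, "record_window", rw)
        if not (0.0 <= rw[0] < rw[1] <= self.duration):
            raise ValueError("record_window must lie within [0, duration]")


class SpikeRecord:
    """Spike events of one simulation run, stored per population.

    ``events`` yields the classic (population, neuron_id, time_ms) triples in
    time order; per-population arrays are the efficient access path.
    """

    def __init__(
        self,
        population_sizes: dict[str, int],
        spikes: dict[str, tuple[np.ndarray, np.ndarray]],
        duration: float,
        t_start: float = 0.0,
    ) -> None:
        self.population_sizes = dict(population_sizes)
        self.duration = float(duration)
        self.t_start = float(t_start)
        self._spikes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pop, (ids, times) in spikes.items():
            ids = np.asarray(ids, dtype=np.int64)
            times = np.asarray(times, dtype=float)
            if ids.size and ids.max() >= self.population_sizes[pop]:
                raise ValueError(f"neuron_id out of range for population {pop}")
            if times.size and (times.min() < 0 or times.max() > duration):
                raise ValueError("spike times must lie within [0, duration]")
            order = np.argsort(times, kind="stable")
            self._spikes[pop] = (ids[order], times[order])
        for pop in self.population_sizes:
            self._spikes.setdefault(pop, (np.empty(0, np.int64), np.empty(0)))

    def spikes_of(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        return self._spikes[population]

    def spike_times(self, population: str) -> np.ndarray:
        return self._spikes[population][1]

    def spike_times_of_neuron(self, population: str, neuron_id: int) -> np.ndarray:
        ids, times = self._spikes[population]
        return times[ids == neuron_id]

    @property
    def n_spikes(self) -> int:
        return sum(t.size for _, t in self._spikes.values())

    @property
    def events(self) -> list[tuple[str, int, float]]:
        all_ev = []
        for pop, (ids, times) in self._spikes.items():
            all_ev.extend(zip([pop] * ids.size, ids.tolist(), times.tolist()))
        all_ev.sort(key=lambda e: e[2])
        return all_ev

    def mean_rate(self, population: str, t_start: float | None = None,
                  t_end: float | None = None) -> float:
        """Mean per-neuron firing rate (Hz) over an interval."""
        t0 = self.t_start if t_start is None else t_start
        t1 = self.duration if t_end is None else t_end
        times = self.spike_times(population)
        n = np.count_nonzero((times >= t0) & (times < t1))
        return n / self.population_sizes[population] / ((t1 - t0) / 1000.0)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# duration_ms={self.duration} t_start_ms={self.t_start}\n")
            fh.write("# sizes=" + ",".join(f"{p}:{n}" for p, n in self.population_sizes.items()) + "\n")
            fh.write("population\tneuron_id\ttime_ms\n")
            for pop, nid, t in self.events:
                fh.write(f"{pop}\t{nid}\t{t:.6g}\n")

    @classmethod
    def load(cls, path: str) -> "SpikeRecord":
        with open(path) as fh:
            meta = fh.readline().strip().lstrip("# ").split()
            duration = float(meta[0].split("=")[1])
            t_start = float(meta[1].split("=")[1])
            sizes_line = fh.readline().strip().lstrip("# ")
            sizes = {}
            for item in sizes_line.split("=", 1)[1].split(","):
                p, n = item.split(":")
                sizes[p] = int(n)
            fh.readline()  # header
            pops, ids, times = [], [], []
            for line in fh:
                p, i, t = line.split()
                pops.append(p); ids.append(int(i)); times.append(float(t))
        spikes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        pops_arr = np.array(pops) if pops else np.empty(0, dtype="U8")
        ids_arr = np.array(ids, dtype=np.int64)
        times_arr = np.array(times)
        for pop in sizes:
            m = pops_arr == pop
            spikes[pop] = (ids_arr[m], times_arr[m])
        return cls(sizes, spikes, duration, t_start)


def poisson_background(
    rate: float,
    n_neurons: int,
    duration: float,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Independent homogeneous Poisson event times (ms) per neuron."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    lam = rate * duration / 1000.0
    for _ in range(n_neurons):
        n = rng.poisson(lam)
        out.append(np.sort(rng.uniform(0.0, duration, n)))
    return out


# ---------------------------------------------------------------------------
# compiled network representation
# ---------------------------------------------------------------------------

class _Compiled:
    """Flat per-neuron parameter arrays and CSR edge lists for the loop."""

    def __init__(self, graph: NetworkGraph, dt: float):
        self.pop_names = [p.name for p in graph.populations]
        self.sizes = [p.size for p in graph.populations]
        self.offsets = {}
        off = 0
        for p in graph.populations:
            self.offsets[p.name] = off
            off += p.size
        self.n = off

        def expand(fn):
            return np.concatenate([np.full(p.size, fn(p.neuron_params)) for p in graph.populations])

        self.C = expand(lambda q: q.membrane_capacitance)
        self.vr = expand(lambda q: q.resting_potential)
        self.vt = expand(lambda q: q.threshold_potential)
        self.vpeak = expand(lambda q: q.peak_cutoff)
        self.vreset = expand(lambda q: q.reset_potential)
        self.a = expand(lambda q: q.recovery_gain)
        self.b = expand(lambda q: q.recovery_sensitivity)
        self.d0 = expand(lambda q: q.after_spike_increment)
        self.k0 = expand(lambda q: q.quadratic_gain)
        self.bias = expand(lambda q: q.bias_current)
        if graph.bias_jitter:
            self.bias = self.bias + np.concatenate(
                [graph.bias_jitter.get(p.name, np.zeros(p.size)) for p in graph.populations]
            )
        self.a2 = expand(lambda q: q.slow2_params.recovery_gain if q.slow2_params else 0.0)
        self.b2 = expand(lambda q: q.slow2_params.recovery_sensitivity if q.slow2_params else 0.0)
        self.d2 = expand(lambda q: q.slow2_params.after_spike_increment if q.slow2_params else 0.0)
        self.w_min = expand(lambda q: q.slow2_params.w_min if q.slow2_params else 0.0)
        self.w_max = expand(lambda q: q.slow2_params.w_max if q.slow2_params else 0.0)

        self.bg_rate = expand_pop(graph, lambda p: p.background_rate)
        self.bg_weight = expand_pop(graph, lambda p: p.background_weight)

        # dopamine membrane coupling slices
        self.d1_slice = self._pop_slice(graph, "D1_MSN")
        self.d2_slice = self._pop_slice(graph, "D2_MSN")
        d1p = graph.population("D1_MSN").neuron_params
        d2p = graph.population("D2_MSN").neuron_params
        self.d1_coupling = d1p.da_coupling
        self.d2_coupling = abs(d2p.da_coupling)
        self.d2_da_current = abs(d2p.da_coupling) * d2p.da_current_scale

        self.dt = dt
        self.rebuild_edges(graph)

    def _pop_slice(self, graph: NetworkGraph, name: str) -> slice:
        off = self.offsets[name]
        return slice(off, off + graph.population(name).size)

    def rebuild_edges(self, graph: NetworkGraph) -> None:
        """(Re)compile the edge lists; called after each STDP batch."""
        src_l, dst_l, w_l, ds_l, ch_l = [], [], [], [], []
        gains: list[float] = [0.0]  # channel 0: dopamine-insensitive
        for proj in graph.projections.values():
            s_off = self.offsets[proj.spec.source]
            t_off = self.offsets[proj.spec.target]
            if proj.spec.da_gain != 0.0:
                try:
                    chan = gains.index(proj.spec.da_gain)
                except ValueError:
                    gains.append(proj.spec.da_gain)
                    chan = len(gains) - 1
            else:
                chan = 0
            src_l.append(proj.src + s_off)
            dst_l.append(proj.dst + t_off)
            w_l.append(proj.weight)
            ds_l.append(np.maximum(1, np.round(proj.delay / self.dt).astype(np.int64)))
            ch_l.append(np.full(proj.src.size, chan, dtype=np.int64))
        if src_l:
            src = np.concatenate(src_l)
            order = np.argsort(src, kind="stable")
            self.e_src = src[order]
            self.e_dst = np.concatenate(dst_l)[order]
            self.e_w = np.concatenate(w_l)[order]
            self.e_dstep = np.concatenate(ds_l)[order]
            self.e_chan = np.concatenate(ch_l)[order]
        else:
            self.e_src = np.empty(0, np.int64)
            self.e_dst = np.empty(0, np.int64)
            self.e_w = np.empty(0)
            self.e_dstep = np.empty(0, np.int64)
            self.e_chan = np.empty(0, np.int64)
        self.indptr = np.searchsorted(self.e_src, np.arange(self.n + 1))
        self.channel_gains = np.asarray(gains)
        self.max_dstep = int(self.e_dstep.max()) if self.e_dstep.size else 1


def expand_pop(graph: NetworkGraph, fn) -> np.ndarray:
    return np.concatenate([np.full(p.size, fn(p)) for p in graph.populations])


def run_simulation(
    graph: NetworkGraph,
    schedule: DopamineSchedule,
    config: SimulationConfig,
) -> SpikeRecord:
    """Integrate the full network and return the recorded spikes.

    Spikes are recorded inside ``config.record_window`` (STDP always sees all
    spikes of its batch).  Deterministic given (graph, schedule, config).
    """
    dt = config.dt
    comp = _Compiled(graph, dt)
    n_steps = int(round(config.duration / dt))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    rng_stdp = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))

    # precompute phi(t) per step
    step_t = np.arange(n_steps) * dt
    phi = np.array([phi_at(schedule, float(t)) for t in step_t[:: max(1, int(1.0 / dt))]])
    # phi sampled every 1 ms, expanded to the step grid (phi varies slowly)
    phi_full = np.repeat(phi, max(1, int(1.0 / dt)))[:n_steps]
    if phi_full.size < n_steps:
        phi_full = np.pad(phi_full, (0, n_steps - phi_full.size), mode="edge")

    # state
    v = comp.vr + rng.uniform(-10.0, 0.0, comp.n)  # desynchronised start
    u = np.zeros(comp.n)
    w = np.zeros(comp.n)
    d_eff = comp.d0.copy()
    i_da = np.zeros(comp.n)

    D = comp.max_dstep + 1
    n_chan = comp.channel_gains.size
    buf = np.zeros((n_chan, D, comp.n))

    # stimulus
    stim = config.stimulus
    stim_current = np.zeros(comp.n)
    scales = stim.target_scales or tuple(1.0 for _ in stim.targets)
    for pop, sc in zip(stim.targets, scales):
        if pop not in comp.offsets:
            raise KeyError(f"stimulus targets unknown population {pop!r}")
        off = comp.offsets[pop]
        size = comp.sizes[comp.pop_names.index(pop)]
        stim_current[off:off + size] = stim.amplitude * sc
    if stim.amplitude != 0.0 and stim.amplitude_jitter > 0:
        j = stim.amplitude_jitter
        stim_current *= rng.uniform(1.0 - j, 1.0 + j, comp.n)
    s0, s1 = stim.window

    # background event probability per step
    lam = comp.bg_rate * dt / 1000.0
    have_bg = np.any(lam > 0)

    rec_lo, rec_hi = config.record_window
    spike_ids: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []
    batch_ids: list[np.ndarray] = []
    batch_steps: list[np.ndarray] = []
    n_resets = 0

    stdp_steps = max(1, int(round(config.stdp_update_interval / dt)))
    plastic = [p for p in graph.projections.values() if p.spec.plastic]

    def apply_stdp(t_now: float) -> None:
        nonlocal batch_ids, batch_steps
        if not (config.stdp_enabled and plastic and batch_ids):
            batch_ids, batch_steps = [], []
            return
        ids_all = np.concatenate(batch_ids)
        t_all = np.concatenate(batch_steps) * dt
        from .connectivity import stdp_update
        for proj in plastic:
            profile = graph.stdp_profiles[proj.spec.stdp_profile]
            pre_spk = _per_neuron(ids_all, t_all, comp, proj.spec.source)
            post_spk = _per_neuron(ids_all, t_all, comp, proj.spec.target)
            stdp_update(graph, profile, pre_spk, post_spk, proj.spec.name,
                        t_now=t_now, rng=rng_stdp)
        comp.rebuild_edges(graph)
        batch_ids, batch_steps = [], []

    for i in range(n_steps):
        t = i * dt
        ph = phi_full[i]
        slot = i % D

        # synaptic + background + stimulus current
        cur = buf[0, slot].copy()
        for c in range(1, n_chan):
            g = corticostriatal_gain(comp.channel_gains[c], ph)
            if g != 0.0:
                cur += g * buf[c, slot]
        buf[:, slot, :] = 0.0
        if have_bg:
            events = rng.poisson(lam)
            cur += events * comp.bg_weight
        if stim.amplitude != 0.0 and s0 <= t < s1:
            cur += stim_current

        # dopamine membrane modulation (matches neurons._effective_coeffs)
        d_eff[comp.d1_slice] = comp.d0[comp.d1_slice] * max(0.0, 1.0 - comp.d1_coupling * ph)
        d_eff[comp.d2_slice] = comp.d0[comp.d2_slice] * max(0.0, 1.0 - comp.d2_coupling * (1.0 - ph))
        i_da[comp.d2_slice] = -comp.d2_da_current * ph

        # reset pass (spike detected at start of step)
        spiked = v >= comp.vpeak
        if spiked.any():
            idx = np.nonzero(spiked)[0]
            n_resets += idx.size
            v[idx] = comp.vreset[idx]
            u[idx] += d_eff[idx]
            w[idx] = np.minimum(w[idx] + comp.d2[idx], comp.w_max[idx])
            if rec_lo <= t < rec_hi:
                spike_ids.append(idx)
                spike_steps.append(np.full(idx.size, i, dtype=np.int64))
            if config.stdp_enabled and plastic:
                batch_ids.append(idx)
                batch_steps.append(np.full(idx.size, i, dtype=np.int64))
            # deliver outgoing pulses
            starts = comp.indptr[idx]
            stops = comp.indptr[idx + 1]
            counts = stops - starts
            if counts.sum() > 0:
                e_idx = _ranges(starts, counts)
                slots = (i + comp.e_dstep[e_idx]) % D
                flat = comp.e_chan[e_idx] * (D * comp.n) + slots * comp.n + comp.e_dst[e_idx]
                np.add.at(buf.reshape(-1), flat, comp.e_w[e_idx])

        # Euler step
        dv = (comp.k0 * (v - comp.vr) * (v - comp.vt) - u - w
              + comp.bias + cur + i_da) / comp.C
        du = comp.a * (comp.b * (v - comp.vr) - u)
        dw = comp.a2 * (comp.b2 * (v - comp.vr) - w)
        v += dt * dv
        u += dt * du
        w += dt * dw
        np.clip(w, comp.w_min, comp.w_max, out=w)
        np.minimum(v, comp.vpeak, out=v)
        np.maximum(v, V_FLOOR, out=v)

        if i % 200 == 0 and not np.all(np.isfinite(v)):
            bad = int(np.nonzero(~np.isfinite(v))[0][0])
            pop, local = _locate(comp, bad)
            raise FloatingPointError(
                f"membrane potential diverged at step {i} (t={t:.1f} ms), "
                f"population {pop}, neuron {local}"
            )

        if config.stdp_enabled and (i + 1) % stdp_steps == 0:
            apply_stdp(t)

    if config.stdp_enabled:
        apply_stdp(n_steps * dt)

    # assemble record
    spikes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if spike_ids:
        all_ids = np.concatenate(spike_ids)
        all_t = np.concatenate(spike_steps) * dt
    else:
        all_ids = np.empty(0, np.int64)
        all_t = np.empty(0)
    for name, size in zip(comp.pop_names, comp.sizes):
        off = comp.offsets[name]
        m = (all_ids >= off) & (all_ids < off + size)
        spikes[name] = (all_ids[m] - off, all_t[m])
    rec = SpikeRecord(graph.population_sizes, spikes, duration=config.duration,
                      t_start=rec_lo)
    rec.n_integrator_resets = n_resets  # event-conservation bookkeeping
    return rec


def _ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate [s, s+c) index ranges (vectorised)."""
    nz = counts > 0
    starts, counts = starts[nz], counts[nz]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    pos = np.cumsum(counts)[:-1]
    out[0] = starts[0]
    out[pos] = starts[1:] - (starts[:-1] + counts[:-1]) + 1
    return np.cumsum(out)


def _locate(comp: _Compiled, global_idx: int) -> tuple[str, int]:
    for name, size in zip(comp.pop_names, comp.sizes):
        off = comp.offsets[name]
        if off <= global_idx < off + size:
            return name, global_idx - off
    raise IndexError(global_idx)


def _per_neuron(ids: np.ndarray, times: np.ndarray, comp: _Compiled, pop: str) -> list[np.ndarray]:
    off = comp.offsets[pop]
    size = comp.sizes[comp.pop_names.index(pop)]
    m = (ids >= off) & (ids < off + size)
    loc = ids[m] - off
    tt = times[m]
    out: list[np.ndarray] = [np.empty(0)] * size
    if loc.size:
        order = np.argsort(loc, kind="stable")
        loc_s, tt_s = loc[order], tt[order]
        bounds = np.searchsorted(loc_s, np.arange(size + 1))
        out = [tt_s[bounds[j]:bounds[j + 1]] for j in range(size)]
    return out
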