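"""Extended Izhikevich point-neuron models for the basal ganglia-thalamo-cortical circuit.

Eight cell types are modelled in the dimensional quadratic (threshold-firing)
form

    C dv/dt = k (v - vr)(v - vt) - u - w + I_bias + I(t) + I_DA
      du/dt = a (b (v - vr) - u)
      dw/dt = a2 (b2 (v - vr) - w)          (thalamocortical relay cells only)

with the auxiliary reset: when ``v`` crosses the peak cutoff the neuron is said
to spike, ``v`` is set to the reset potential, ``u`` is incremented by the
after-spike increment ``d`` and, for TC cells, ``w`` by ``d2``.

The second slow variable ``w`` is a slow, linear recovery process standing in
for the de-inactivation of low-threshold calcium conductances: holding a TC
cell hyperpolarised drives ``w`` negative, and on release the accumulated
``-w`` acts as a transient depolarising drive that produces a rebound burst.

Dopamine enters the medium-spiny-neuron (MSN) dynamics through a single signed
coupling coefficient (positive for D1, negative for D2):

* D1-MSN: the after-spike increment is scaled by ``(1 - |c| * phi)``, so a
  higher dopamine level weakens spike-frequency adaptation.  This raises the
  slope of the f-I curve while leaving the subthreshold phase portrait - and
  hence the rheobase - exactly unchanged.
* D2-MSN: the mirror image - the after-spike increment is scaled by
  ``(1 - |c| * (1 - phi))`` and a tonic hyperpolarising current
  ``|c| * da_current_scale * phi`` (pA) is subtracted, so a higher dopamine
  level suppresses D2 excitability while dopamine depletion (phi -> 0)
  leaves the D2 population maximally excitable (the indirect-pathway
  dominance underlying the Parkinsonian resting state).

Autonomously pacemaking nuclei (GPe, GPi, STN) carry an intrinsic bias
current, so their rheobase with respect to *injected* current is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CELL_TYPES",
    "NeuronParams",
    "NeuronState",
    "StimulusProtocol",
    "Slow2Params",
    "load_neuron_params",
    "step_neuron",
    "simulate_neuron",
    "f_i_curve",
    "find_rheobase",
    "phase_portrait",
    "bifurcation_scan",
    "DT_STABILITY_CAP",
]

CELL_TYPES = (
    "D1_MSN",
    "D2_MSN",
    "GPe",
    "GPi",
    "STN",
    "CTX_RS",
    "CTX_FS",
    "TC",
)

#: hard cap on the explicit-Euler step (ms); beyond this the quadratic model
#: can overshoot the peak cutoff by hundreds of mV within one step.
DT_STABILITY_CAP = 1.0

#: hyperpolarisation floor (mV).  Real membranes are bounded near the K+
#: reversal potential; the bare quadratic term grows without bound below
#: rest and would catapult the voltage upward after a strong inhibitory
#: volley, so the integrator clamps v at this floor.
V_FLOOR = -100.0


@dataclass(frozen=True)
class Slow2Params:
    """Second slow-variable coefficients (TC relay cells only).

    The variable is clamped to ``[w_min, w_max]``: it stands in for a
    low-threshold calcium conductance whose de-inactivation (negative w,
    rebound drive) and inactivation (positive w, burst termination) both
    saturate.  The floor sets the maximal rebound charge a hyperpolarised
    cell can accumulate.
    """

    recovery_gain: float      # a2, 1/ms
    recovery_sensitivity: float  # b2, pA/mV
    after_spike_increment: float  # d2, pA
    w_min: float = -150.0     # pA, de-inactivation saturation
    w_max: float = 100.0      # pA, inactivation saturation


@dataclass(frozen=True)
class NeuronParams:
    cell_type: str
    membrane_capacitance: float   # C, pF
    resting_potential: float      # vr, mV
    threshold_potential: float    # vt, mV
    peak_cutoff: float            # vpeak, mV
    reset_potential: float        # c, mV
    recovery_gain: float          # a, 1/ms
    recovery_sensitivity: float   # b, pA/mV
    after_spike_increment: float  # d, pA
    quadratic_gain: float         # k, pA/mV^2 (conductance-like)
    bias_current: float = 0.0     # pA, intrinsic pacemaker drive
    da_coupling: float = 0.0      # signed; >0 for D1_MSN, <0 for D2_MSN
    da_current_scale: float = 0.0  # pA per unit phi (D2 hyperpolarising term)
    slow2_params: Slow2Params | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        for name in (
            "membrane_capacitance", "resting_potential", "threshold_potential",
            "peak_cutoff", "reset_potential", "recovery_gain",
            "recovery_sensitivity", "after_spike_increment", "quadratic_gain",
            "bias_current", "da_coupling", "da_current_scale",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"NeuronParams.{name} is not finite")
        if not (self.reset_potential < self.threshold_potential < self.peak_cutoff):
            raise ValueError(
                "require reset_potential < threshold_potential < peak_cutoff, got "
                f"{self.reset_potential} / {self.threshold_potential} / {self.peak_cutoff}"
            )
        if (self.slow2_params is not None) != (self.cell_type == "TC"):
            raise ValueError("slow2_params must be present iff cell_type == 'TC'")
        if self.da_coupling != 0.0 and self.cell_type not in ("D1_MSN", "D2_MSN"):
            raise ValueError("da_coupling must be zero for non-MSN cell types")
        if self.cell_type == "D1_MSN" and self.da_coupling < 0:
            raise ValueError("D1_MSN da_coupling must be >= 0 (dopamine excites D1)")
        if self.cell_type == "D2_MSN" and self.da_coupling > 0:
            raise ValueError("D2_MSN da_coupling must be <= 0 (dopamine inhibits D2)")


@dataclass
class NeuronState:
    v: float
    u: float = 0.0
    w: float = 0.0
    last_spike_time: float | None = None

    def validate(self) -> None:
        for name in ("v", "u", "w"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"NeuronState.{name} is not finite")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered current-injection segments with a constant dopamine level."""

    segments: tuple[tuple[float, float], ...]  # (duration ms, current pA)
    dopamine_level: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple((float(d), float(i)) for d, i in self.segments))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be > 0")
        if not 0.0 <= self.dopamine_level <= 1.0:
            raise ValueError("dopamine_level must lie in [0, 1]")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def current_at(self, t: float) -> float:
        edge = 0.0
        for dur, cur in self.segments:
            edge += dur
            if t < edge:
                return cur
        return self.segments[-1][1]


def resting_state(params: NeuronParams) -> NeuronState:
    """Initial condition at the nominal resting potential with relaxed recovery."""
    v = params.resting_potential
    return NeuronState(v=v, u=0.0, w=0.0)


# ---------------------------------------------------------------------------
# dopamine-modulated effective coefficients
# ---------------------------------------------------------------------------

def _effective_coeffs(params: NeuronParams, phi: float) -> tuple[float, float, float]:
    """Return (k_eff, d_eff, i_da) for the given dopamine level."""
    k = params.quadratic_gain
    d = params.after_spike_increment
    i_da = 0.0
    if params.cell_type == "D1_MSN":
        d = d * max(0.0, 1.0 - params.da_coupling * phi)
    elif params.cell_type == "D2_MSN":
        c = abs(params.da_coupling)
        d = d * max(0.0, 1.0 - c * (1.0 - phi))
        i_da = -c * params.da_current_scale * phi
    return k, d, i_da


# ---------------------------------------------------------------------------
# single-step integration
# ---------------------------------------------------------------------------

def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    injected_current: float,
    phi: float,
    dt: float,
    t: float | None = None,
) -> tuple[NeuronState, bool]:
    """One explicit-Euler step; returns the new state and a spike flag.

    The spike time convention is the start-of-step timestamp of the step in
    which the crossing is detected.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if dt > DT_STABILITY_CAP:
        raise ValueError(f"dt={dt} exceeds the stability cap of {DT_STABILITY_CAP} ms")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if not math.isfinite(injected_current):
        raise ValueError("injected_current is not finite")
    state.validate()

    k, d_eff, i_da = _effective_coeffs(params, phi)
    v, u, w = state.v, state.u, state.w
    spike = v >= params.peak_cutoff
    if spike:
        v = params.reset_potential
        u = u + d_eff
        if params.slow2_params is not None:
            w = w + params.slow2_params.after_spike_increment

    dv = (
        k * (v - params.resting_potential) * (v - params.threshold_potential)
        - u - w + params.bias_current + injected_current + i_da
    ) / params.membrane_capacitance
    du = params.recovery_gain * (
        params.recovery_sensitivity * (v - params.resting_potential) - u
    )
    v_new = v + dt * dv
    u_new = u + dt * du
    if params.slow2_params is not None:
        s2 = params.slow2_params
        w_new = w + dt * s2.recovery_gain * (
            s2.recovery_sensitivity * (v - params.resting_potential) - w
        )
        w_new = min(max(w_new, s2.w_min), s2.w_max)
    else:
        w_new = w
    v_new = min(max(v_new, V_FLOOR), params.peak_cutoff)
    new = NeuronState(
        v=v_new, u=u_new, w=w_new,
        last_spike_time=(t if (spike and t is not None) else state.last_spike_time),
    )
    return new, spike


def simulate_neuron(
    params: NeuronParams,
    protocol: StimulusProtocol,
    dt: float = 0.1,
    initial_state: NeuronState | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one neuron through a current protocol.

    Returns ``(times, voltage_trace, spike_times)``.  Deterministic given
    (params, protocol, dt).  The loop works on plain floats for speed; the
    semantics match :func:`step_neuron` exactly (shared reset convention).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if dt > DT_STABILITY_CAP:
        raise ValueError(f"dt={dt} exceeds the stability cap of {DT_STABILITY_CAP} ms")
    phi = protocol.dopamine_level
    k, d_eff, i_da = _effective_coeffs(params, phi)

    C = params.membrane_capacitance
    vr = params.resting_potential
    vt = params.threshold_potential
    vpeak = params.peak_cutoff
    vreset = params.reset_potential
    a = params.recovery_gain
    b = params.recovery_sensitivity
    bias = params.bias_current + i_da
    s2 = params.slow2_params
    have_w = s2 is not None

    n_steps = int(round(protocol.total_duration / dt))
    times = np.arange(n_steps) * dt
    trace = np.empty(n_steps)
    spikes: list[float] = []

    st = initial_state if initial_state is not None else resting_state(params)
    v, u, w = st.v, st.u, st.w

    # precompute the per-step current from the segment structure
    current = np.empty(n_steps)
    edge = 0.0
    i0 = 0
    for dur, cur in protocol.segments:
        edge += dur
        i1 = min(n_steps, int(round(edge / dt)))
        current[i0:i1] = cur
        i0 = i1
    if i0 < n_steps:
        current[i0:] = protocol.segments[-1][1]

    for i in range(n_steps):
        if v >= vpeak:
            spikes.append(times[i])
            v = vreset
            u += d_eff
            if have_w:
                w = min(w + s2.after_spike_increment, s2.w_max)
        trace[i] = v
        dv = (k * (v - vr) * (v - vt) - u - w + bias + current[i]) / C
        du = a * (b * (v - vr) - u)
        if have_w:
            w += dt * s2.recovery_gain * (s2.recovery_sensitivity * (v - vr) - w)
            w = min(max(w, s2.w_min), s2.w_max)
        v += dt * dv
        u += dt * du
        if not math.isfinite(v):
            raise FloatingPointError(
                f"membrane potential diverged at t={times[i]:.2f} ms for {params.cell_type}"
            )
        if v > vpeak:
            v = vpeak
        elif v < V_FLOOR:
            v = V_FLOOR
    return times, trace, np.asarray(spikes)


# ---------------------------------------------------------------------------
# f-I characterisation
# ---------------------------------------------------------------------------

def _steady_rate(spike_times: np.ndarray, trial_duration: float) -> float:
    """Firing frequency from the mean inter-spike interval over the final
    half of the trial (discards the adaptation transient)."""
    half = trial_duration / 2.0
    late = spike_times[spike_times >= half]
    if late.size < 2:
        return 0.0
    isi = np.diff(late).mean()
    return 1000.0 / isi


def f_i_curve(
    params: NeuronParams,
    phi: float,
    current_grid: Sequence[float],
    trial_duration: float = 2000.0,
    dt: float = 0.1,
) -> list[tuple[float, float]]:
    """Steady-state firing frequency (Hz) per injected-current level (pA)."""
    grid = list(current_grid)
    if not grid:
        raise ValueError("current_grid must not be empty")
    if any(b > a for a, b in zip(grid[1:], grid[:-1])):
        raise ValueError("current_grid must be sorted ascending")
    out = []
    for cur in grid:
        proto = StimulusProtocol(segments=((trial_duration, cur),), dopamine_level=phi)
        _, _, spikes = simulate_neuron(params, proto, dt=dt)
        out.append((float(cur), _steady_rate(spikes, trial_duration)))
    return out


def _fires_sustained(params: NeuronParams, phi: float, current: float,
                     trial_duration: float, dt: float) -> bool:
    proto = StimulusProtocol(segments=((trial_duration, current),), dopamine_level=phi)
    _, _, spikes = simulate_neuron(params, proto, dt=dt)
    return spikes[spikes >= trial_duration / 2.0].size >= 2


def find_rheobase(
    params: NeuronParams,
    phi: float = 0.5,
    dt: float = 0.1,
    tol: float = 1.0,
    lower: float = -1000.0,
    upper: float = 1000.0,
    trial_duration: float = 2000.0,
) -> float:
    """Minimal sustained-spiking current found by bisection, to within ``tol`` pA."""
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if not _fires_sustained(params, phi, upper, trial_duration, dt):
        raise RuntimeError(f"no sustained spiking at the upper search bound {upper} pA")
    if _fires_sustained(params, phi, lower, trial_duration, dt):
        raise RuntimeError(f"still spiking at the lower search bound {lower} pA")
    lo, hi = lower, upper
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _fires_sustained(params, phi, mid, trial_duration, dt):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# phase-plane analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Equilibrium:
    v: float
    u: float
    stability: str  # "stable" | "unstable" | "saddle"
    eigenvalues: tuple[complex, complex]


@dataclass(frozen=True)
class PhasePortrait:
    v_grid: np.ndarray
    v_nullcline: np.ndarray  # u = k (v-vr)(v-vt) + I_total on the grid
    u_nullcline: np.ndarray  # u = b (v-vr)
    equilibria: tuple[Equilibrium, ...]
    complete: bool


def _total_bias(params: NeuronParams, injected_current: float, phi: float) -> float:
    _, _, i_da = _effective_coeffs(params, phi)
    return params.bias_current + injected_current + i_da


def _planar_b(params: NeuronParams) -> float:
    # the TC second slow variable is frozen at its fixed point w* = b2 (v - vr),
    # which folds into the planar subsystem as an additional linear term
    b = params.recovery_sensitivity
    if params.slow2_params is not None:
        b += params.slow2_params.recovery_sensitivity
    return b


def phase_portrait(
    params: NeuronParams,
    injected_current: float,
    phi: float = 0.5,
    v_range: tuple[float, float] | None = None,
    n_grid: int = 400,
) -> PhasePortrait:
    """Nullclines and classified equilibria of the planar (v, u) subsystem."""
    k, _, _ = _effective_coeffs(params, phi)
    vr, vt = params.resting_potential, params.threshold_potential
    b = _planar_b(params)
    itot = _total_bias(params, injected_current, phi)
    if v_range is None:
        v_range = (vr - 30.0, params.peak_cutoff)
    v_grid = np.linspace(v_range[0], v_range[1], n_grid)
    v_null = k * (v_grid - vr) * (v_grid - vt) + itot
    u_null = b * (v_grid - vr)

    # equilibria: k (v-vr)(v-vt) - b (v-vr) + itot = 0  (quadratic in v)
    coeffs = [k, -k * (vr + vt) - b, k * vr * vt + b * vr + itot]
    roots = np.roots(coeffs)
    eqs: list[Equilibrium] = []
    complete = True
    a = params.recovery_gain
    C = params.membrane_capacitance
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        v0 = float(r.real)
        if not (v_range[0] <= v0 <= v_range[1]):
            continue
        u0 = b * (v0 - vr)
        # Jacobian of the planar subsystem
        j11 = k * (2 * v0 - vr - vt) / C
        j12 = -1.0 / C
        j21 = a * b
        j22 = -a
        tr = j11 + j22
        det = j11 * j22 - j12 * j21
        disc = complex(tr * tr - 4 * det) ** 0.5
        lam = ((tr + disc) / 2, (tr - disc) / 2)
        if det < 0:
            stability = "saddle"
        elif tr < 0:
            stability = "stable"
        else:
            stability = "unstable"
        eqs.append(Equilibrium(v=v0, u=u0, stability=stability,
                               eigenvalues=(complex(lam[0]), complex(lam[1]))))
    eqs.sort(key=lambda e: e.v)
    return PhasePortrait(v_grid=v_grid, v_nullcline=v_null, u_nullcline=u_null,
                         equilibria=tuple(eqs), complete=complete)


def bifurcation_scan(
    params: NeuronParams,
    currents: Iterable[float],
    phi: float = 0.5,
    v_range: tuple[float, float] | None = None,
) -> list[tuple[float, int]]:
    """Number of subthreshold equilibria per injected current.

    The current at which the count drops from 2 to 0 is the saddle-node
    bifurcation and coincides with the rheobase.
    """
    out = []
    for cur in currents:
        pp = phase_portrait(params, cur, phi=phi, v_range=v_range)
        out.append((float(cur), len(pp.equilibria)))
    return out


# ---------------------------------------------------------------------------
# parameter-file loading
# ---------------------------------------------------------------------------

def load_neuron_params(path: str | None = None) -> dict[str, NeuronParams]:
    """Load the per-cell-type parameter tables (packaged defaults if no path)."""
    import yaml

    if path is None:
        from importlib.resources import files
        text = (files("bgloop") / "data" / "neuron_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, NeuronParams] = {}
    for cell_type, fields_ in raw.items():
        fields_ = dict(fields_)
        s2 = fields_.pop("slow2_params", None)
        if s2 is not None:
            s2 = Slow2Params(**s2)
        out[cell_type] = NeuronParams(cell_type=cell_type, slow2_params=s2, **fields_)
    return out


def with_dopamine(params: NeuronParams, da_coupling: float) -> NeuronParams:
    return replace(params, da_coupling=da_coupling)
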