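"""Time-varying dopamine level phi(t) with tonic and phasic components.

The tonic component is the steady-state extracellular dopamine concentration;
the phasic component is the rapid, stimulus-locked release triggered whenever
the cortex is stimulated.  During a stimulus window

    phi(t) = phi_tonic + phi_phasic,

and after the window ends the phasic part decays exponentially back toward
the tonic baseline.  The exponential decay with a 500 ms time constant is the
package's minimal smooth model of the post-stimulus fall-off; onset is
instantaneous at window start.  The bound phi_tonic + phi_phasic <= 1 keeps
phi(t) in [0, 1] at all times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DopamineSchedule", "phi_at", "split_receptor_levels"]


@dataclass(frozen=True)
class DopamineSchedule:
    phi_tonic: float
    phi_phasic: float = 0.0
    stimulus_windows: tuple[tuple[float, float], ...] = ()
    decay_time_constant: float = 500.0  # ms
    decay_form: str = "exponential"  # recorded in run metadata

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "stimulus_windows",
            tuple((float(a), float(b)) for a, b in self.stimulus_windows),
        )
        if self.phi_tonic < 0 or self.phi_phasic < 0:
            raise ValueError("phi_tonic and phi_phasic must be >= 0")
        if self.phi_tonic + self.phi_phasic > 1.0:
            raise ValueError(
                f"phi_tonic + phi_phasic = {self.phi_tonic + self.phi_phasic} "
                "must lie in [0, 1]"
            )
        if self.decay_time_constant <= 0:
            raise ValueError("decay_time_constant must be > 0")
        wins = sorted(self.stimulus_windows)
        for (a0, b0), (a1, b1) in zip(wins, wins[1:]):
            if a1 < b0:
                raise ValueError(
                    f"overlapping stimulus windows {(a0, b0)} and {(a1, b1)}: "
                    "the phasic trigger is ill-defined"
                )
        for a, b in wins:
            if b <= a:
                raise ValueError(f"empty stimulus window {(a, b)}")


def phi_at(schedule: DopamineSchedule, t: float) -> float:
    """Dopamine level at time t (ms)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if schedule.phi_phasic == 0.0:
        return schedule.phi_tonic
    phasic = 0.0
    for a, b in schedule.stimulus_windows:
        if a <= t < b:
            phasic = schedule.phi_phasic
            break
        if t >= b:
            decayed = schedule.phi_phasic * np.exp(-(t - b) / schedule.decay_time_constant)
            phasic = max(phasic, float(decayed))
    return min(1.0, schedule.phi_tonic + phasic)


def split_receptor_levels(phi: float) -> tuple[float, float]:
    """Receptor-specific dopamine levels (phi1 for D1, phi2 for D2).

    Both receptor families track the same extracellular level, so this
    returns (phi, phi); kept as a seam for receptor-specific schedules.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return (phi, phi)
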