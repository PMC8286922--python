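"""Configuration files, run manifests, and report rendering.

A run is driven by one YAML document with layered precedence (scenario
preset < user file < command-line overrides) and all randomness flows from a
single master seed.  The manifest written next to the outputs records enough
to re-run any repetition bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .scenarios import SCENARIO_SETTINGS, ScenarioConfig, scenario_config

__all__ = ["load_config", "save_config", "validate_config", "RunManifest",
           "render_report", "ConfigError"]


class ConfigError(ValueError):
    """Raised with every violated invariant listed in the message."""


_KNOWN_KEYS = {
    "scenario", "master_seed", "warmup_ms", "analysis_length_ms",
    "n_repetitions", "dt_ms", "phi_tonic", "phi_phasic",
    "gpi_thalamus_scale", "stimulus_enabled", "out_dir",
}


def validate_config(raw: Mapping[str, Any]) -> list[str]:
    """Return the list of violated invariants (empty when valid)."""
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    sc = raw.get("scenario")
    if sc is not None and sc not in SCENARIO_SETTINGS:
        errors.append(f"scenario must be one of {sorted(SCENARIO_SETTINGS)}, got {sc!r}")
    pt = raw.get("phi_tonic")
    pp = raw.get("phi_phasic")
    if pt is not None and pt < 0:
        errors.append("phi_tonic must be >= 0")
    if pp is not None and pp < 0:
        errors.append("phi_phasic must be >= 0")
    if pt is not None and pp is not None and pt + pp > 1.0:
        errors.append(f"phi_tonic + phi_phasic = {pt + pp} exceeds 1")
    scale = raw.get("gpi_thalamus_scale")
    if scale is not None and not (0.0 < scale <= 1.0):
        errors.append("gpi_thalamus_scale must lie in (0, 1]")
    for key in ("warmup_ms", "analysis_length_ms", "dt_ms"):
        v = raw.get(key)
        if v is not None and v <= 0:
            errors.append(f"{key} must be > 0")
    nrep = raw.get("n_repetitions")
    if nrep is not None and (int(nrep) != nrep or nrep < 1):
        errors.append("n_repetitions must be a positive integer")
    return errors


def load_config(path: str) -> ScenarioConfig:
    """Load and validate a full run configuration."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"{path}: empty configuration file")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    errors = validate_config(raw)
    if errors:
        raise ConfigError(f"{path}: " + "; ".join(errors))
    if "scenario" not in raw:
        raise ConfigError(f"{path}: 'scenario' is required")
    overrides = {}
    for src, dst in (("phi_tonic", "phi_tonic"), ("phi_phasic", "phi_phasic"),
                     ("gpi_thalamus_scale", "gpi_thalamus_scale"),
                     ("stimulus_enabled", "stimulus_enabled"),
                     ("n_repetitions", "n_repetitions")):
        if src in raw:
            overrides[dst] = raw[src]
    return scenario_config(
        raw["scenario"],
        warmup=float(raw.get("warmup_ms", 600_000.0 - 7000.0)),
        analysis_length=float(raw.get("analysis_length_ms", 7000.0)),
        n_repetitions=int(raw.get("n_repetitions", 20)),
        dt=float(raw.get("dt_ms", 0.5)),
        overrides=overrides or None,
    )


def save_config(cfg: ScenarioConfig, path: str) -> None:
    raw = {
        "scenario": cfg.id,
        "phi_tonic": cfg.phi_tonic,
        "phi_phasic": cfg.phi_phasic,
        "gpi_thalamus_scale": cfg.gpi_thalamus_scale,
        "stimulus_enabled": cfg.stimulus_enabled,
        "n_repetitions": cfg.n_repetitions,
        "dt_ms": cfg.sim.dt,
        "warmup_ms": cfg.sim.record_window[0],
        "analysis_length_ms": cfg.sim.duration - cfg.sim.record_window[0],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    repetition_seeds: list[int]
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path: str) -> None:
        doc = asdict(self)
        doc["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            doc = json.load(fh)
        doc.pop("config_hash", None)
        return cls(**doc)

    @staticmethod
    def now() -> str:
        return time.strftime("%Y-%m-%dT%H:%M:%S")


def render_report(
    manifest: RunManifest,
    records: Sequence,
    out_dir: str,
    populations: Sequence[str] = ("CTX_RS", "D1_MSN", "D2_MSN", "GPe", "GPi", "STN", "TC"),
) -> dict:
    """Figures and a summary table for one scenario's repetitions.

    Per population: a raster of the first repetition with the
    repetition-averaged firing rate overlaid, plus a spectrogram and power
    histogram from the averaged rate; and one summary table row (dominant
    frequency, band, mean rate, synchrony).  Missing populations are listed
    in the returned dict under ``missing`` and the partial report is still
    produced.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .analysis import averaged_rate, firing_rate, spectral_summary, synchrony_index

    os.makedirs(out_dir, exist_ok=True)
    table: list[dict] = []
    missing: list[str] = []
    rec0 = records[0]
    t0, t1 = rec0.t_start, rec0.duration
    for pop in populations:
        if pop not in rec0.population_sizes:
            missing.append(pop)
            continue
        ids, times = rec0.spikes_of(pop)
        coarse = averaged_rate(records, pop, window_length=50.0, stride=50.0,
                               t_start=t0, t_end=t1)
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(times / 1000.0, ids, ".k", markersize=1)
        ax2 = ax.twinx()
        ax2.plot(coarse.times / 1000.0, coarse.rate, color="green", lw=1.5,
                 label=f"mean rate ({len(records)} runs)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("neuron")
        ax2.set_ylabel("rate (Hz)")
        ax.set_title(f"{pop}: raster (run 1) + average firing rate")
        fig.tight_layout()
        raster_path = os.path.join(out_dir, f"raster_{pop}.png")
        fig.savefig(raster_path, dpi=110)
        plt.close(fig)

        fine = averaged_rate(records, pop, window_length=2.0, stride=2.0,
                             t_start=t0, t_end=t1)
        try:
            summ = spectral_summary(fine)
        except ValueError:
            missing.append(f"{pop} (series too short for spectra)")
            continue
        fig, (axa, axb) = plt.subplots(1, 2, figsize=(9, 3))
        axa.pcolormesh(summ.spectrogram_times / 1000.0, summ.frequencies,
                       10 * np.log10(summ.spectrogram + 1e-12), shading="auto")
        axa.set_xlabel("time (s)")
        axa.set_ylabel("frequency (Hz)")
        axa.set_title(f"{pop} spectrogram")
        axb.plot(summ.frequencies, summ.power_histogram)
        axb.set_xlabel("frequency (Hz)")
        axb.set_ylabel("power")
        axb.set_title("power histogram")
        fig.tight_layout()
        spec_path = os.path.join(out_dir, f"spectrum_{pop}.png")
        fig.savefig(spec_path, dpi=110)
        plt.close(fig)

        sync = float(np.nanmean([synchrony_index(r, [pop], 10.0, t0, t1) for r in records]))
        table.append({
            "population": pop,
            "dominant_frequency_hz": summ.dominant_frequency,
            "band": summ.band,
            "mean_rate_hz": float(np.mean([r.mean_rate(pop, t0, t1) for r in records])),
            "synchrony_index": sync,
            "raster": raster_path,
            "spectrum": spec_path,
        })
    table_path = os.path.join(out_dir, "summary.tsv")
    with open(table_path, "w") as fh:
        cols = ["population", "dominant_frequency_hz", "band", "mean_rate_hz", "synchrony_index"]
        fh.write("\t".join(cols) + "\n")
        for row in table:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    manifest.outputs.append(table_path)
    return {"table": table, "table_path": table_path, "missing": missing}
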