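"""Population firing rates, spectral summaries, synchrony, and VAR/PDC coupling.

The analysis pipeline mirrors how local-field-potential proxies are read off a
spiking simulation:

1. raster -> windowed population firing rate (50 ms reporting window; a finer
   2 ms stride grid is used for spectral work so beta/gamma content stays
   below Nyquist);
2. rate series -> short-time spectral estimate (Hann window, linear detrend),
   time-averaged into a power histogram, with the dominant frequency and its
   frequency-band label (theta 4-8, alpha 8-13, beta 13-30, gamma 30-150 Hz);
3. multivariate rate series -> vector autoregressive (VAR) fit and partial
   directed coherence (PDC / generalised PDC) between populations.

Rates are normalised per neuron (spikes / window / population size) so that
populations of different sizes are comparable; the raw population-summed
convention is available behind ``per_neuron=False`` and is recorded on the
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "BAND_EDGES",
    "FiringRateSeries",
    "SpectralSummary",
    "PdcResult",
    "classify_band",
    "firing_rate",
    "average_rates",
    "spectral_summary",
    "var_pdc",
    "synchrony_index",
    "detect_rebound_bursts",
]

#: half-open [low, high) frequency bands, Hz
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 150.0),
}


def classify_band(frequency: float) -> str:
    """Band label for a frequency; half-open edges so 13 Hz is beta, 30 Hz gamma."""
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    for name, (lo, hi) in BAND_EDGES.items():
        if lo <= frequency < hi:
            return name
    return "above_gamma"


@dataclass
class FiringRateSeries:
    population: str
    times: np.ndarray          # window centres, ms
    rate: np.ndarray           # Hz
    window_length: float = 50.0  # ms
    stride: float = 50.0         # ms
    n_runs_averaged: int = 1
    per_neuron: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.shape != self.rate.shape:
            raise ValueError("times and rate must have the same shape")
        if np.any(self.rate < -1e-12):
            raise ValueError("rates must be >= 0")


def firing_rate(
    record,
    population: str,
    window_length: float = 50.0,
    stride: float | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
    per_neuron: bool = True,
) -> FiringRateSeries:
    """Windowed firing rate of one population from a spike record.

    Windows are half-open ``[t, t + T)`` placed every ``stride`` ms; the rate
    is spike count / window length (seconds), divided by the population size
    when ``per_neuron`` (the default).
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    stride = window_length if stride is None else stride
    if not 0 < stride <= window_length:
        raise ValueError("stride must satisfy 0 < stride <= window_length")
    if population not in record.population_sizes:
        raise KeyError(f"unknown population {population!r}")
    t0 = 0.0 if t_start is None else float(t_start)
    t1 = record.duration if t_end is None else float(t_end)

    times = record.spike_times(population)
    times = times[(times >= t0) & (times < t1)]
    n_windows = max(0, int(np.floor((t1 - t0 - window_length) / stride)) + 1)
    starts = t0 + stride * np.arange(n_windows)
    if window_length == stride:
        counts = np.histogram(times, bins=np.append(starts, starts[-1] + stride) if n_windows else [t0, t1])[0]
        counts = counts[:n_windows].astype(float)
    else:
        # overlapping windows: cumulative-count difference at window edges
        sorted_times = np.sort(times)
        lo = np.searchsorted(sorted_times, starts, side="left")
        hi = np.searchsorted(sorted_times, starts + window_length, side="left")
        counts = (hi - lo).astype(float)
    rate = counts / (window_length / 1000.0)
    if per_neuron:
        rate = rate / record.population_sizes[population]
    return FiringRateSeries(
        population=population,
        times=starts + window_length / 2.0,
        rate=rate,
        window_length=window_length,
        stride=stride,
        per_neuron=per_neuron,
    )


def average_rates(series: Sequence[FiringRateSeries]) -> FiringRateSeries:
    """Pointwise mean of rate series sharing one population and window grid."""
    if not series:
        raise ValueError("need at least one series")
    ref = series[0]
    for s in series[1:]:
        if s.population != ref.population:
            raise ValueError("all series must be for the same population")
        if (s.window_length != ref.window_length or s.stride != ref.stride
                or s.times.shape != ref.times.shape
                or not np.allclose(s.times, ref.times)):
            raise ValueError("mismatched window grids")
        if s.per_neuron != ref.per_neuron:
            raise ValueError("mixed rate normalisations")
    mean = np.mean([s.rate for s in series], axis=0)
    return FiringRateSeries(
        population=ref.population, times=ref.times.copy(), rate=mean,
        window_length=ref.window_length, stride=ref.stride,
        n_runs_averaged=sum(s.n_runs_averaged for s in series),
        per_neuron=ref.per_neuron,
    )


@dataclass
class SpectralSummary:
    population: str
    frequencies: np.ndarray            # Hz
    spectrogram_times: np.ndarray      # ms
    spectrogram: np.ndarray            # power, (freq, time)
    power_histogram: np.ndarray        # time-averaged power per frequency bin
    dominant_frequency: float | None   # None when the series is flat
    band: str | None
    synchrony_index: float             # fraction of non-DC power in dominant band


def spectral_summary(
    rate: FiringRateSeries,
    segment_length: float = 1000.0,
    overlap: float = 0.5,
    max_frequency: float = 150.0,
) -> SpectralSummary:
    """Short-time spectral estimate of a firing-rate series.

    Hann-windowed, linearly detrended segments of ``segment_length`` ms with
    fractional ``overlap``; the power histogram is the time average of the
    spectrogram.  The dominant frequency is the argmax of the histogram
    excluding the DC bin, and the band label follows the half-open band
    edges.  A constant series has no dominant frequency (flagged ``None``).
    """
    fs = 1000.0 / rate.stride  # Hz
    nper = int(round(segment_length / rate.stride))
    if nper < 8:
        raise ValueError("segment_length too short for the series stride")
    if rate.rate.size < nper:
        raise ValueError(
            f"series of {rate.rate.size} samples is shorter than one "
            f"{nper}-sample segment"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if max_frequency > fs / 2:
        raise ValueError(
            f"stride of {rate.stride} ms caps the analysis at {fs / 2:.1f} Hz "
            f"(Nyquist); requested {max_frequency} Hz needs a finer-stride series"
        )
    noverlap = int(round(nper * overlap))
    freqs, times_s, sxx = signal.spectrogram(
        rate.rate, fs=fs, window="hann", nperseg=nper, noverlap=noverlap,
        detrend="linear", scaling="density", mode="psd",
    )
    df = freqs[1] - freqs[0]
    keep = freqs <= max_frequency
    freqs, sxx = freqs[keep], sxx[keep] * df  # power per bin: Parseval-exact
    hist = sxx.mean(axis=1)
    non_dc = freqs > 0
    total = hist[non_dc].sum()
    if total <= 1e-12 * max(1.0, float(np.mean(rate.rate)) ** 2):
        dom: float | None = None
        band: str | None = None
        sync = 0.0
    else:
        idx = np.argmax(hist[non_dc])
        dom = float(freqs[non_dc][idx])
        band = classify_band(dom)
        lo, hi = BAND_EDGES.get(band, (dom, np.inf))
        in_band = non_dc & (freqs >= lo) & (freqs < hi)
        sync = float(hist[in_band].sum() / total)
    return SpectralSummary(
        population=rate.population,
        frequencies=freqs,
        spectrogram_times=times_s * 1000.0 + rate.times[0],
        spectrogram=sxx,
        power_histogram=hist,
        dominant_frequency=dom,
        band=band,
        synchrony_index=sync,
    )


@dataclass
class PdcResult:
    populations: tuple[str, ...]
    frequencies: np.ndarray   # Hz
    pdc: np.ndarray           # (target, source, freq), column-normalised
    gpdc: np.ndarray          # generalised PDC
    model_order: int


def var_pdc(
    rates: Sequence[FiringRateSeries],
    model_order: int = 10,
    n_frequencies: int = 128,
    select_order_aic: bool = False,
) -> PdcResult:
    """VAR fit of multivariate rate series and partial directed coherence.

    ``pdc[i, j, f]`` is the coupling from source j to target i at frequency
    f; each source column's squared magnitudes sum to 1 at every frequency.
    The generalised PDC additionally weights entries by the inverse residual
    standard deviations.
    """
    if len(rates) < 2:
        raise ValueError("need at least two populations")
    ref = rates[0]
    for s in rates[1:]:
        if s.times.shape != ref.times.shape or not np.allclose(s.times, ref.times):
            raise ValueError("rate series must share a common time grid")
    if model_order < 1:
        raise ValueError("model_order must be >= 1")
    from statsmodels.tsa.api import VAR

    data = np.column_stack([s.rate for s in rates])
    data = data - data.mean(axis=0)
    k = data.shape[1]
    model = VAR(data)
    try:
        if select_order_aic:
            res = model.fit(maxlags=model_order, ic="aic")
            if res.k_ar == 0:
                res = model.fit(model_order)
        else:
            res = model.fit(model_order)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            f"VAR fit of order {model_order} is rank deficient; try a lower order"
        ) from exc
    order = res.k_ar
    coefs = res.coefs  # (order, k, k)
    sigma = np.asarray(res.sigma_u)

    fs = 1000.0 / ref.stride
    freqs = np.linspace(0, fs / 2, n_frequencies)
    # A_bar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)
    r = np.arange(1, order + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs / fs, r))  # (F, order)
    a_bar = np.eye(k)[None, :, :] - np.einsum("fr,rij->fij", phase, coefs)

    mag2 = np.abs(a_bar) ** 2                      # (F, i, j)
    denom = np.sqrt(mag2.sum(axis=1))              # (F, j): column norms
    pdc = np.abs(a_bar) / np.where(denom[:, None, :] == 0, 1.0, denom[:, None, :])

    w = 1.0 / np.sqrt(np.clip(np.diag(sigma), 1e-300, None))  # (i,)
    gmag2 = (w[None, :, None] * np.abs(a_bar)) ** 2
    gdenom = np.sqrt(gmag2.sum(axis=1))
    gpdc = (w[None, :, None] * np.abs(a_bar)) / np.where(gdenom[:, None, :] == 0, 1.0, gdenom[:, None, :])

    return PdcResult(
        populations=tuple(s.population for s in rates),
        frequencies=freqs,
        pdc=np.moveaxis(pdc, 0, -1),
        gpdc=np.moveaxis(gpdc, 0, -1),
        model_order=order,
    )


def synchrony_index(
    record,
    populations: Sequence[str],
    window: float = 10.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Mean pairwise correlation of binned spike counts across neurons.

    Spike counts are binned at ``window`` ms per neuron, pooled over the
    listed populations; the mean off-diagonal Pearson correlation is clipped
    to [0, 1].  Neurons that never spike in the interval carry no correlation
    information and are excluded; if fewer than two active neurons remain the
    index is undefined and NaN is returned (never silently 0).
    """
    if not populations:
        raise ValueError("need at least one population")
    t0 = 0.0 if t_start is None else float(t_start)
    t1 = record.duration if t_end is None else float(t_end)
    edges = np.arange(t0, t1 + window, window)
    rows = []
    for pop in populations:
        if pop not in record.population_sizes:
            raise KeyError(f"unknown population {pop!r}")
        ids, times = record.spikes_of(pop)
        m = (times >= t0) & (times < t1)
        ids, times = ids[m], times[m]
        n = record.population_sizes[pop]
        counts = np.zeros((n, edges.size - 1))
        if times.size:
            bin_idx = np.minimum(((times - t0) / window).astype(int), edges.size - 2)
            np.add.at(counts, (ids, bin_idx), 1.0)
        rows.append(counts)
    counts = np.vstack(rows)
    active = counts.std(axis=1) > 0
    if active.sum() < 2:
        return float("nan")
    corr = np.corrcoef(counts[active])
    n_act = corr.shape[0]
    off = (corr.sum() - np.trace(corr)) / (n_act * (n_act - 1))
    return float(np.clip(off, 0.0, 1.0))


def averaged_rate(
    records: Sequence,
    population: str | Sequence[str],
    window_length: float = 2.0,
    stride: float = 2.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> FiringRateSeries:
    """Repetition-averaged firing-rate series: rates are computed per run,
    then averaged pointwise across runs so the spectral estimate stabilises.  ``population`` may be a list, in which
    case the populations' pooled spikes form one subnetwork series (rates
    are per neuron of the pooled subnetwork)."""
    pops = [population] if isinstance(population, str) else list(population)
    per_run = []
    for rec in records:
        series = [firing_rate(rec, p, window_length, stride, t_start, t_end)
                  for p in pops]
        if len(series) == 1:
            per_run.append(series[0])
        else:
            sizes = np.array([rec.population_sizes[p] for p in pops], dtype=float)
            pooled = sum(s.rate * n for s, n in zip(series, sizes)) / sizes.sum()
            per_run.append(FiringRateSeries(
                population="+".join(pops), times=series[0].times, rate=pooled,
                window_length=window_length, stride=stride))
    return average_rates(per_run)


def detect_rebound_bursts(
    spike_times: np.ndarray,
    min_spikes: int = 3,
    max_isi: float = 12.0,
    min_quiet: float = 30.0,
) -> list[tuple[float, int]]:
    """Rebound bursts in one neuron's spike train.

    A burst is a run of >= ``min_spikes`` consecutive spikes with inter-spike
    intervals <= ``max_isi`` ms, preceded by at least ``min_quiet`` ms of
    silence (the hallmark of post-inhibitory rebound rather than tonic
    firing).  Returns (burst start time, spike count) per burst.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if t.size < min_spikes:
        return []
    isi = np.diff(t)
    bursts: list[tuple[float, int]] = []
    i = 0
    while i < t.size:
        # the record start carries no history, so it cannot count as quiet
        quiet_before = i > 0 and isi[i - 1] >= min_quiet
        j = i
        while j < t.size - 1 and isi[j] <= max_isi:
            j += 1
        run = j - i + 1
        if quiet_before and run >= min_spikes:
            bursts.append((float(t[i]), int(run)))
        i = j + 1
    return bursts
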