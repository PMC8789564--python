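"""Synthetic recordings with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: LFP sessions across wake / NREM / moderate / deep-anesthesia
states (deep = burst-suppression alternation with a recorded
segmentation, optional injected epileptiform transients), lognormal
single-unit spike trains with state-dependent multiplicative gains,
calcium event rasters with co-activation motifs and scheduled network
bursts, and MEA hourly-rate trajectories with perturbation profiles.

A single global seed is expanded into independent per-generator
substreams by stable hashing of the generator name, so adding one
generator never perturbs another's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import IntervalSet, SignalTrace, SpikeTrain
from .core import EventRaster
from .errors import InvalidParameterError
from .spikes import gain_factor

LFP_STATES = ("wake", "NREM", "moderate", "deep")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator substream derived from (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SynthGroundTruth:
    """Ground truth accompanying one synthetic dataset."""

    seg_truth: IntervalSet | None = None          # burst/suppression segmentation
    epi_times: np.ndarray | None = None           # injected transient times, s
    unit_gain_truth: pd.DataFrame | None = None   # base_rate_hz, nrem_multiplier, true_gain_pct
    motif_truth: np.ndarray | None = None         # per-frame motif id, 0 = background
    burst_schedule: list | None = None            # (bin, participation_frac)
    mea_truth: pd.DataFrame | None = None         # baseline_hz, stable, profile columns


# ------------------------------------------------------------------ LFP


@dataclass
class LfpParams:
    """Amplitude/duration parameters of the LFP session generator.

    Amplitudes are in mV; the study reports no per-state amplitude scales,
    so these are free parameters with documented defaults chosen to keep
    the qualitative ordering (wake low-amplitude/high-frequency, NREM
    delta-dominated high amplitude, deep alternating bursts and near-flat
    suppressions with an SD ratio of 10:1).
    """

    rate: float = 1000.0
    wake_background_sd: float = 0.05
    theta_amp: float = 0.04
    theta_band: tuple[float, float] = (6.0, 9.0)
    nrem_background_sd: float = 0.05
    delta_amp: float = 0.15
    delta_band: tuple[float, float] = (1.0, 4.0)
    burst_sd: float = 0.20
    suppression_sd: float = 0.02
    burst_band: tuple[float, float] = (1.0, 50.0)
    burst_dur_mean_s: float = 5.0
    burst_dur_min_s: float = 2.5
    suppression_dur_mean_s: float = 5.0
    suppression_dur_min_s: float = 2.5
    emg_wake_sd: float = 0.10
    emg_rest_sd: float = 0.02
    n_epileptiform: int = 0
    epi_amp_sd: float = 15.0
    epi_refractory_s: float = 0.1
    epi_width_s: float = 0.02

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LfpParams":
        d = dict(d)
        for k in ("theta_band", "delta_band", "burst_band"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spectrum / np.sqrt(f), n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_noise(rng, n, rate, band):
    x = rng.standard_normal(n)
    if n > 30:
        sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_duration(rng, mean_s, min_s):
    # shifted exponential: all segments >= min_s, mean = mean_s
    return min_s + rng.exponential(mean_s - min_s)


def simulate_lfp_session(
    plan: Sequence[tuple[str, float]],
    params: LfpParams | None = None,
    seed: int = 0,
) -> tuple[SignalTrace, SignalTrace, IntervalSet, SynthGroundTruth]:
    """Simulate an LFP + EMG session following a state plan.

    ``plan`` is an ordered list of ``(state, duration_s)`` with state in
    {wake, NREM, moderate, deep}. Deep segments alternate broadband
    high-variance bursts with near-flat suppressions drawn from shifted
    exponential duration distributions; every segment is recorded in the
    ground-truth segmentation. Optional epileptiform transients (biphasic,
    ``epi_amp_sd`` background SDs) are injected at random times with a
    refractory constraint and recorded in ``epi_times``.
    """
    p = params or LfpParams()
    if p.burst_sd < 0 or p.suppression_sd < 0 or p.epi_amp_sd < 0:
        raise InvalidParameterError("amplitudes must be nonnegative")
    for state, dur in plan:
        if state not in LFP_STATES:
            raise InvalidParameterError(f"unknown state {state!r}")
        if not dur > 0:
            raise InvalidParameterError("durations must be > 0")

    rng = substream(seed, "lfp")
    rate = p.rate
    lfp_parts: list[np.ndarray] = []
    emg_parts: list[np.ndarray] = []
    hyp: list[tuple[float, float, str]] = []
    seg: list[tuple[float, float, str]] = []
    t = 0.0

    for state, dur in plan:
        n = int(round(dur * rate))
        if state == "wake":
            theta_f = rng.uniform(*p.theta_band)
            phase = rng.uniform(0, 2 * np.pi)
            x = p.wake_background_sd * _pink_noise(rng, n) + p.theta_amp * np.sin(
                2 * np.pi * theta_f * np.arange(n) / rate + phase
            )
            emg = p.emg_wake_sd * rng.standard_normal(n)
        elif state in ("NREM", "moderate"):
            delta_f = rng.uniform(*p.delta_band)
            phase = rng.uniform(0, 2 * np.pi)
            x = p.nrem_background_sd * _pink_noise(rng, n) + p.delta_amp * np.sin(
                2 * np.pi * delta_f * np.arange(n) / rate + phase
            )
            emg = p.emg_rest_sd * rng.standard_normal(n)
        else:  # deep: burst-suppression alternation
            carrier = _bandlimited_noise(rng, n, rate, p.burst_band)
            envelope = np.empty(n)
            pos = 0.0
            is_burst = True
            while pos < dur:
                seg_dur = _draw_duration(
                    rng,
                    p.burst_dur_mean_s if is_burst else p.suppression_dur_mean_s,
                    p.burst_dur_min_s if is_burst else p.suppression_dur_min_s,
                )
                end = min(pos + seg_dur, dur)
                i0, i1 = int(round(pos * rate)), int(round(end * rate))
                envelope[i0:i1] = p.burst_sd if is_burst else p.suppression_sd
                seg.append((t + pos, t + end, "burst" if is_burst else "suppression"))
                pos = end
                is_burst = not is_burst
            x = carrier * envelope
            emg = p.emg_rest_sd * rng.standard_normal(n)
        lfp_parts.append(x)
        emg_parts.append(emg)
        hyp.append((t, t + dur, state))
        t += dur

    lfp = np.concatenate(lfp_parts)
    emg = np.concatenate(emg_parts)
    total_dur = t

    epi_times = np.array([])
    if p.n_epileptiform > 0:
        background_sd = float(lfp.std())
        width_n = int(round(p.epi_width_s * rate))
        half = width_n // 2
        # draw start times with a minimum spacing of the refractory interval
        times: list[float] = []
        guard = 0
        lo_t, hi_t = 0.1, total_dur - p.epi_width_s - 0.1
        while len(times) < p.n_epileptiform:
            cand = float(rng.uniform(lo_t, hi_t))
            if all(abs(cand - x) >= p.epi_refractory_s + p.epi_width_s for x in times):
                times.append(cand)
            guard += 1
            if guard > 100_000:
                raise InvalidParameterError("cannot place transients with this refractory")
        times.sort()
        amp = p.epi_amp_sd * background_sd
        tt = np.arange(width_n) / rate
        pulse = np.where(
            tt < p.epi_width_s / 2,
            amp * np.sin(2 * np.pi * tt / p.epi_width_s),
            -0.7 * amp * np.sin(2 * np.pi * (tt - p.epi_width_s / 2) / p.epi_width_s),
        )
        peaks = []
        for t0 in times:
            i0 = int(round(t0 * rate))
            lfp[i0 : i0 + width_n] += pulse[: max(0, lfp.size - i0)]
            peaks.append(t0 + p.epi_width_s / 4)  # positive-lobe peak
        epi_times = np.asarray(peaks)

    truth = SynthGroundTruth(
        seg_truth=IntervalSet(seg) if seg else IntervalSet([]),
        epi_times=epi_times,
    )
    return (
        SignalTrace(lfp, rate=rate, label="lfp", units="mV"),
        SignalTrace(emg, rate=rate, label="emg", units="mV"),
        IntervalSet(hyp),
        truth,
    )


# ------------------------------------------------------------- spike trains

#: NREM multipliers per median-split subgroup producing the preset median
#: gains: gain(m) = 100*(m-1)/max(1,m), so 0.79 -> -21% and 1/0.88 -> +12%.
GAIN_PRESETS = {
    "WT_like": {"below_median": 1.0, "above_median": 0.79},
    "APP_like": {"below_median": 1.0 / 0.88, "above_median": 1.0},
}


def simulate_spike_trains(
    n_units: int,
    rate_distribution: tuple[float, float],
    hypnogram: IntervalSet,
    gain_preset: str | dict = "WT_like",
    multiplier_jitter: float = 0.10,
    seed: int = 0,
) -> tuple[list[SpikeTrain], SynthGroundTruth]:
    """Inhomogeneous-Poisson spike trains with state-dependent gains.

    Base (active-wake) rates are lognormal(mu, sigma); each unit fires at
    its base rate in active_wake and at base rate x multiplier in NREM.
    The preset draws multipliers (lognormal jitter around the subgroup
    multiplier) so the implied gains have the preset's median per
    median-split subgroup. The drawn multipliers and implied gains are
    recorded in ``unit_gain_truth``.
    """
    if n_units < 2:
        raise InvalidParameterError("need at least 2 units")
    mu, sigma = rate_distribution
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    states = hypnogram.labels
    if "active_wake" not in states or "NREM" not in states:
        raise InvalidParameterError("hypnogram must contain active_wake and NREM")
    if isinstance(gain_preset, str):
        if gain_preset not in GAIN_PRESETS:
            raise InvalidParameterError(f"unknown preset {gain_preset!r}")
        preset = GAIN_PRESETS[gain_preset]
    else:
        preset = dict(gain_preset)

    rng = substream(seed, "spikes")
    base = rng.lognormal(mu, sigma, size=n_units)
    above = base > np.median(base)
    mult = np.where(above, preset["above_median"], preset["below_median"]) * np.exp(
        rng.normal(0.0, multiplier_jitter, size=n_units)
    )
    true_gain = np.array([gain_factor(b * m, b) for b, m in zip(base, mult)])

    trains: list[SpikeTrain] = []
    for u in range(n_units):
        times_parts = []
        for s, e, l in hypnogram:
            rate = base[u] * (mult[u] if l == "NREM" else 1.0)
            n = rng.poisson(rate * (e - s))
            times_parts.append(rng.uniform(s, e, size=n))
        times = np.unique(np.concatenate(times_parts))
        trains.append(
            SpikeTrain(
                unit_id=f"u{u:03d}",
                times=times,
                isi_violation_frac=0.0,
                isolation_distance=20.0,
                unit_class="RS",
            )
        )
    truth = SynthGroundTruth(
        unit_gain_truth=pd.DataFrame(
            {
                "unit_id": [t.unit_id for t in trains],
                "base_rate_hz": base,
                "nrem_multiplier": mult,
                "true_gain_pct": true_gain,
                "above_median": above,
            }
        )
    )
    return trains, truth


# ----------------------------------------------------------------- rasters


def simulate_ca_raster(
    n_cells: int,
    n_frames: int,
    motifs: Sequence[Sequence[int]] = (),
    motif_rate: float = 0.0,
    burst_schedule: Sequence[tuple[int, float]] = (),
    baseline_p: float = 0.01,
    frame_rate: float = 10.0,
    seed: int = 0,
) -> tuple[EventRaster, SynthGroundTruth]:
    """Calcium event raster with motifs and scheduled network bursts.

    Background frames activate each cell independently with ``baseline_p``;
    motif frames (Bernoulli ``motif_rate`` per frame, motif drawn
    uniformly) activate the motif's cell subset on top of the background;
    scheduled bursts activate ``participation_frac`` of all cells within
    their 100-ms bin. Amplitudes are lognormal. ``motif_truth`` records the
    per-frame motif id (0 = background) and ``burst_schedule`` is echoed
    into the ground truth.
    """
    if not 0 <= baseline_p < 1:
        raise InvalidParameterError("baseline_p must lie in [0, 1)")
    for m in motifs:
        if any(c < 0 or c >= n_cells for c in m):
            raise InvalidParameterError("motif references a nonexistent cell")
    for b, frac in burst_schedule:
        if not 0 < frac <= 1:
            raise InvalidParameterError("participation_frac must lie in (0, 1]")

    rng = substream(seed, "raster")
    active = rng.random((n_cells, n_frames)) < baseline_p
    motif_truth = np.zeros(n_frames, dtype=int)

    if len(motifs) > 0 and motif_rate > 0:
        motif_frames = np.flatnonzero(rng.random(n_frames) < motif_rate)
        which = rng.integers(0, len(motifs), size=motif_frames.size)
        for f, k in zip(motif_frames, which):
            active[np.asarray(motifs[k], int), f] = True
            motif_truth[f] = k + 1

    frames_per_bin = max(1, int(round(0.1 * frame_rate)))
    for b, frac in burst_schedule:
        f0 = b * frames_per_bin
        if f0 >= n_frames:
            raise InvalidParameterError(f"burst bin {b} beyond the raster")
        k = int(round(frac * n_cells))
        cells = rng.choice(n_cells, size=k, replace=False)
        active[cells, f0] = True

    events = np.where(active, rng.lognormal(0.0, 0.5, size=(n_cells, n_frames)), 0.0)
    truth = SynthGroundTruth(
        motif_truth=motif_truth, burst_schedule=[(int(b), float(f)) for b, f in burst_schedule]
    )
    return EventRaster(events=events, frame_rate=frame_rate), truth


# -------------------------------------------------------------------- MEA


def simulate_mea_rates(
    n_channels: int,
    baseline_hours: int,
    perturbation: tuple[float, float, float | None] | None = None,
    instability_channels: Sequence[int] = (),
    total_hours: int | None = None,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, SynthGroundTruth]:
    """Hourly per-channel MFR series with an optional step perturbation.

    ``perturbation`` is ``(onset_h, immediate_fraction, recovery_tau_h)``:
    at onset the rate drops to ``immediate_fraction`` of baseline and, when
    a recovery time constant is given, relaxes exponentially back toward
    baseline (MFR renormalization). Channels listed in
    ``instability_channels`` drift by more than 30% during the baseline and
    are flagged unstable in the ground truth.
    """
    if not baseline_hours > 0:
        raise InvalidParameterError("baseline_hours must be > 0")
    if perturbation is not None:
        onset, frac, tau = perturbation
        if onset < baseline_hours:
            raise InvalidParameterError("perturbation onset must follow the baseline")
        if not frac > 0:
            raise InvalidParameterError("immediate_fraction must be > 0")
    total = total_hours if total_hours is not None else baseline_hours + 24

    rng = substream(seed, "mea")
    hours = np.arange(total)
    baseline_hz = rng.lognormal(0.0, 0.5, size=n_channels)
    profile = np.ones(total)
    if perturbation is not None:
        onset, frac, tau = perturbation
        post = hours >= onset
        if tau is not None:
            profile[post] = frac + (1 - frac) * (1 - np.exp(-(hours[post] - onset) / tau))
        else:
            profile[post] = frac

    unstable = np.zeros(n_channels, bool)
    unstable[list(instability_channels)] = True
    data = np.empty((n_channels, total))
    for ch in range(n_channels):
        prof = profile.copy()
        if unstable[ch]:
            # alternating +-40% swing during the baseline window
            swing = 0.4 * np.where(np.arange(baseline_hours) % 2 == 0, 1.0, -1.0)
            prof[:baseline_hours] *= 1.0 + swing
        data[ch] = baseline_hz[ch] * prof * np.exp(rng.normal(0, noise_sigma, total))

    rates = pd.DataFrame(
        data, index=[f"ch{c:03d}" for c in range(n_channels)], columns=hours
    )
    truth = SynthGroundTruth(
        mea_truth=pd.DataFrame(
            {
                "channel": rates.index,
                "baseline_hz": baseline_hz,
                "stable": ~unstable,
            }
        )
    )
    return rates, truth
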