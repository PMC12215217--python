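"""Synthetic REM-sleep polysomnography with known ground truth.

Generates EEG whose power spectrum follows a state-dependent piecewise power
law (steeper low band and flatter high band during phasic REM), bilateral EOG
with scripted conjugate rapid-eye-movement (EM) events clustered in bursts on
an infra-slow (~2 min) timescale, and the ground-truth epoch labels, event
list and generative exponents needed to validate every downstream stage.

Spectral synthesis is exact: Gaussian noise is shaped in the frequency
domain so the *expected* one-sided PSD equals the target power law at every
bin, which makes slope recovery an analytic property rather than an
approximation.  Below ``f_floor`` the PSD is held flat to bound spectral
leakage from frequencies outside the analysis bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import AREA_CHANNELS, EOG_CHANNELS, SCORING_EPOCH_S, Recording

__all__ = [
    "SyntheticSpec",
    "ScriptedEvent",
    "GroundTruth",
    "synth_aperiodic_signal",
    "schedule_em_bursts",
    "synth_eog",
    "synth_rem_episode",
    "synth_cohort",
    "synth_coupled_series",
    "write_episode",
]

#: Analysis epoch length (s); matches the spectral module grid.
EPOCH_S = 4.0

#: PSD is flat below this frequency (Hz) to limit leakage into the 2-30 Hz
#: fitting band from the unanalysed < 2 Hz range.
F_FLOOR = 1.0

#: Low/high band break frequency of the piecewise power law (Hz).
F_BREAK = 30.0



@dataclass
class SyntheticSpec:
    """Generative parameters of one synthetic REM episode.

    Exponents are the target slopes of log-power vs log-frequency
    (dimensionless, negative in sleep).  Defaults place the tonic state at
    the REM-typical ``-2.1`` (low band) / ``-3.9`` (high band) and make the
    phasic state steeper by 0.15 in the low band and flatter by 0.4 in the
    high band.  ``oscillations`` are (centre Hz, peak ratio) pairs rendered
    as Gaussian PSD bumps, the ratio being oscillatory-to-fractal power at
    the centre frequency.
    """

    sample_rate: float = 250.0
    duration: float = 600.0
    low_exponent_tonic: float = -2.1
    low_exponent_phasic: float = -2.25
    high_exponent_tonic: float = -3.9
    high_exponent_phasic: float = -3.5
    oscillations: tuple[tuple[float, float], ...] = ((5.0, 1.0),)
    em_burst_period: float = 120.0
    em_burst_duration: float = 16.0
    em_rate_in_burst: float = 0.7
    em_amplitude_median: float = 180.0
    em_amplitude_sigma_log: float = 0.3
    em_amplitude_min: float = 150.0
    eog_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("low_exponent_tonic", "low_exponent_phasic",
                     "high_exponent_tonic", "high_exponent_phasic"):
            a = getattr(self, name)
            if not np.isfinite(a) or a > 0:
                raise ValueError(f"{name} must be finite and <= 0, got {a}")
        f_top = 48.0 * 1.9  # highest analysis frequency times largest h
        if self.sample_rate / 2 <= f_top:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz too low: IRASA on the "
                f"30-48 Hz band with h=1.9 needs Nyquist > {f_top:.0f} Hz"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ScriptedEvent:
    """One scheduled rapid eye movement (ground truth)."""

    onset: float
    duration: float
    amplitude: float

    @property
    def peak_time(self) -> float:
        """Time of the deflection extremum (centre of the leading lobe)."""
        return self.onset + self.duration / 2

    @property
    def end(self) -> float:
        """End of the full biphasic waveform (two lobes of ``duration`` each)."""
        return self.onset + 2 * self.duration


@dataclass
class GroundTruth:
    """Per-epoch labels, scripted events and generative exponents."""

    epoch_labels: np.ndarray  # "phasic" | "tonic" | "unclassified", per 4-s epoch
    em_events: list[ScriptedEvent]
    true_exponents: pd.DataFrame  # columns: epoch_index, band, exponent
    phasic_weight: np.ndarray = field(repr=False, default=None)  # per sample


def _shaped_noise(
    psd: np.ndarray, sample_rate: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise whose expected one-sided PSD equals ``psd`` per rfft bin."""
    n_bins = n // 2 + 1
    scale = np.sqrt(psd * sample_rate * n / 2.0)
    re = rng.standard_normal(n_bins)
    im = rng.standard_normal(n_bins)
    spec = scale * (re + 1j * im) / np.sqrt(2.0)
    spec[0] = 0.0  # zero mean
    if n % 2 == 0:
        spec[-1] = scale[-1] * re[-1]
    return np.fft.irfft(spec, n=n)


def _piecewise_psd(
    freqs: np.ndarray,
    alpha_low: float,
    alpha_high: float,
    oscillations: tuple[tuple[float, float], ...] = (),
    ref_power: float = 5.0,
) -> np.ndarray:
    """Piecewise power-law PSD (uV^2/Hz), continuous at ``F_BREAK``.

    ``ref_power`` anchors the absolute scale at 10 Hz.  Oscillations enter
    multiplicatively as Gaussian bumps of 0.5 Hz width.
    """
    f = np.maximum(freqs, F_FLOOR)
    c = ref_power / 10.0**alpha_low
    low = c * f**alpha_low
    high = c * F_BREAK ** (alpha_low - alpha_high) * f**alpha_high
    psd = np.where(f <= F_BREAK, low, high)
    bump = np.ones_like(psd)
    for f0, ratio in oscillations:
        bump += ratio * np.exp(-((freqs - f0) ** 2) / (2 * 0.5**2))
    return psd * bump


def synth_aperiodic_signal(
    exponent: float,
    sample_rate: float,
    duration: float,
    seed: int,
    oscillations: tuple[tuple[float, float], ...] = (),
) -> np.ndarray:
    """Zero-mean noise with expected PSD proportional to ``f**exponent``.

    The power law holds exactly from ``F_FLOOR`` to Nyquist; identical
    arguments yield bit-identical output.
    """
    if not np.isfinite(exponent) or exponent > 0:
        raise ValueError(f"exponent must be finite and <= 0, got {exponent}")
    n = int(round(duration * sample_rate))
    if n < 2:
        raise ValueError("duration * sample_rate must be at least 2 samples")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    f = np.maximum(freqs, F_FLOOR)
    psd = 5.0 / 10.0**exponent * f**exponent
    bump = np.ones_like(psd)
    for f0, ratio in oscillations:
        bump += ratio * np.exp(-((freqs - f0) ** 2) / (2 * 0.5**2))
    return _shaped_noise(psd * bump, sample_rate, n, rng)


def _draw_amplitude(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    """Log-normal amplitude, truncated below the phasic-defining threshold."""
    mu = np.log(spec.em_amplitude_median)
    for _ in range(100):
        a = float(np.exp(mu + spec.em_amplitude_sigma_log * rng.standard_normal()))
        if a >= spec.em_amplitude_min:
            return a
    return spec.em_amplitude_min


def schedule_em_bursts(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[ScriptedEvent]:
    """Clustered EM point process: bursts recurring every ``em_burst_period`` s.

    Burst centres are jittered by up to 10 % of the period; within a burst,
    inter-event intervals are uniform in ``[0.8, 1.2] / em_rate_in_burst`` so
    that consecutive events fall in adjacent 2-s windows (the phasic
    criterion).  Event durations are uniform in 0.1-0.5 s; no two waveforms
    overlap.
    """
    if spec.em_burst_period <= 0:
        raise ValueError("em_burst_period must be positive")
    if spec.em_rate_in_burst == 0:
        return []
    max_span = 2 * 0.5  # two lobes of at most 0.5 s each
    if 0.8 / spec.em_rate_in_burst <= max_span:
        raise ValueError(
            f"em_rate_in_burst={spec.em_rate_in_burst}/s leaves intervals "
            f"shorter than one event waveform ({max_span} s); non-overlap infeasible"
        )
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    events: list[ScriptedEvent] = []
    n_bursts = int(spec.duration // spec.em_burst_period)
    for k in range(n_bursts):
        centre = (k + 0.5) * spec.em_burst_period
        centre += rng.uniform(-0.1, 0.1) * spec.em_burst_period
        t = centre - spec.em_burst_duration / 2
        stop = centre + spec.em_burst_duration / 2
        while t < stop:
            dur = rng.uniform(0.1, 0.5)
            if 1.0 < t and t + 2 * dur < spec.duration - 1.0:
                events.append(ScriptedEvent(onset=t, duration=dur,
                                            amplitude=_draw_amplitude(spec, rng)))
            t += rng.uniform(0.8, 1.2) / spec.em_rate_in_burst
    return events


def _render_event(ev: ScriptedEvent, sample_rate: float, n: int) -> tuple[int, np.ndarray]:
    """One-cycle biphasic waveform: two opposite sine lobes of equal duration
    and amplitude.  Zero net area, so band-pass filtering leaves no slow
    baseline tail."""
    i0 = int(round(ev.onset * sample_rate))
    n_wave = max(int(round(2 * ev.duration * sample_rate)), 4)
    t = np.arange(n_wave) / sample_rate
    wave = ev.amplitude * np.sin(np.pi * t / ev.duration)
    end = min(i0 + wave.size, n)
    return i0, wave[: end - i0]


def synth_eog(
    em_events: list[ScriptedEvent],
    sample_rate: float,
    duration: float,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilateral EOG: conjugate (anti-phase) event waveforms plus noise.

    Event polarity alternates randomly (saccade direction); the right
    channel carries the mirrored waveform at 95 % gain.  ``noise_sd`` must
    stay below the 25-uV tonic quiescence bound, otherwise a warning is
    issued because tonic ground truth would be contaminated.
    """
    if noise_sd >= 25.0:
        warnings.warn(
            f"noise_sd={noise_sd} uV reaches the 25-uV tonic quiescence bound; "
            "tonic ground-truth labels may be invalid",
            stacklevel=2,
        )
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    left = rng.standard_normal(n) * noise_sd
    right = rng.standard_normal(n) * noise_sd
    for ev in em_events:
        if ev.onset < 0 or ev.end > duration:
            raise ValueError(f"event at {ev.onset:.2f} s does not fit inside signal")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i0, wave = _render_event(ev, sample_rate, n)
        left[i0 : i0 + wave.size] += sign * wave
        right[i0 : i0 + wave.size] -= 0.95 * sign * wave
    return left, right


def _phasic_weight(
    events: list[ScriptedEvent], sample_rate: float, n: int, fade: float = 0.5
) -> np.ndarray:
    """Phasic-state power weight per sample: 1 inside burst spans, 0 in tonic
    stretches, raised-cosine transitions over ``fade`` seconds."""
    w = np.zeros(n)
    if not events:
        return w
    # merge events separated by < 4 s into burst intervals, pad by 1 s
    spans: list[list[float]] = []
    for ev in sorted(events, key=lambda e: e.onset):
        if spans and ev.onset - spans[-1][1] < 4.0:
            spans[-1][1] = ev.end
        else:
            spans.append([ev.onset, ev.end])
    n_fade = max(int(round(fade * sample_rate)), 2)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_fade)))
    for s0, s1 in spans:
        i0 = int(round((s0 - 1.0) * sample_rate))
        i1 = int(round((s1 + 1.0) * sample_rate))
        a, b = max(i0, 0), min(i1, n)
        w[a:b] = 1.0
        if i0 - n_fade >= 0:
            w[i0 - n_fade : i0] = np.maximum(w[i0 - n_fade : i0], ramp)
        if i1 + n_fade <= n:
            w[i1 : i1 + n_fade] = np.maximum(w[i1 : i1 + n_fade], ramp[::-1])
    return w


def _epoch_ground_truth(
    events: list[ScriptedEvent], spec: SyntheticSpec, weight: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    n_epochs = int(spec.duration // EPOCH_S)
    peak_windows = {int(ev.peak_time // 2.0) for ev in events}
    touched: set[int] = set()  # 2-s windows overlapped by any waveform
    for ev in events:
        for win in range(int(ev.onset // 2.0), int(ev.end // 2.0) + 1):
            touched.add(win)
    labels = np.full(n_epochs, "unclassified", dtype=object)
    for k in range(n_epochs):
        w0, w1 = 2 * k, 2 * k + 1
        if w0 in peak_windows and w1 in peak_windows:
            labels[k] = "phasic"
        elif not touched & {w0 - 1, w0, w1, w1 + 1}:
            labels[k] = "tonic"
    step = int(EPOCH_S * spec.sample_rate)
    rows = []
    for k in range(n_epochs):
        phasic = weight[k * step : (k + 1) * step].mean() > 0.5
        rows.append({"epoch_index": k, "band": "low",
                     "exponent": spec.low_exponent_phasic if phasic else spec.low_exponent_tonic})
        rows.append({"epoch_index": k, "band": "high",
                     "exponent": spec.high_exponent_phasic if phasic else spec.high_exponent_tonic})
    return labels.astype(str), pd.DataFrame(rows)


def synth_rem_episode(
    spec: SyntheticSpec, participant: str = "sim01"
) -> tuple[Recording, GroundTruth]:
    """One REM episode: EEG with state-switched exponents, EOG, ground truth.

    EEG for each area is an equal-power crossfade (0.5-s raised cosine)
    between two independent shaped-noise streams with the tonic and phasic
    piecewise power laws; channels within an area duplicate the area-level
    source, since independent per-channel noise would add a white floor that
    distorts the high-band spectrum.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / spec.sample_rate)
    events = schedule_em_bursts(spec, rng)
    weight = _phasic_weight(events, spec.sample_rate, n)
    w_p = np.sqrt(weight)
    w_t = np.sqrt(1.0 - weight)

    psd_tonic = _piecewise_psd(freqs, spec.low_exponent_tonic,
                               spec.high_exponent_tonic, spec.oscillations)
    psd_phasic = _piecewise_psd(freqs, spec.low_exponent_phasic,
                                spec.high_exponent_phasic, spec.oscillations)
    channels: dict[str, np.ndarray] = {}
    for area, labels in AREA_CHANNELS.items():
        tonic_stream = _shaped_noise(psd_tonic, spec.sample_rate, n, rng)
        phasic_stream = _shaped_noise(psd_phasic, spec.sample_rate, n, rng)
        sig = w_t * tonic_stream + w_p * phasic_stream
        for lb in labels:
            channels[lb] = sig

    eog_seed = int(rng.integers(2**31))
    left, right = synth_eog(events, spec.sample_rate, spec.duration,
                            spec.eog_noise_sd, seed=eog_seed)
    channels[EOG_CHANNELS[0]] = left
    channels[EOG_CHANNELS[1]] = right

    hypnogram = np.full(int(np.ceil(spec.duration / SCORING_EPOCH_S)), "R")
    rec = Recording(channels=channels, sample_rate=spec.sample_rate,
                    hypnogram=hypnogram, metadata={"participant": participant})
    labels, exponents = _epoch_ground_truth(events, spec, weight)
    return rec, GroundTruth(epoch_labels=labels, em_events=events,
                            true_exponents=exponents, phasic_weight=weight)


def synth_cohort(
    n_participants: int,
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    baseline_sd: float = 0.15,
) -> list[tuple[Recording, GroundTruth]]:
    """Cohort of episodes with participant-specific baseline exponents.

    One normal baseline offset per participant shifts all four exponents
    (both bands, both states): between-subject variation in broadband slope
    is shared across bands, and the within-subject phasic-tonic difference
    stays constant across participants, as in a within-subject design.
    """
    spec = spec or SyntheticSpec()
    root = np.random.default_rng(seed)
    out = []
    for i in range(n_participants):
        d = root.normal(0, baseline_sd)
        p_spec = SyntheticSpec(
            **{
                **asdict(spec),
                "low_exponent_tonic": spec.low_exponent_tonic + d,
                "low_exponent_phasic": spec.low_exponent_phasic + d,
                "high_exponent_tonic": spec.high_exponent_tonic + d,
                "high_exponent_phasic": spec.high_exponent_phasic + d,
                "seed": int(root.integers(2**31)),
            }
        )
        out.append(synth_rem_episode(p_spec, participant=f"sim{i + 1:02d}"))
    return out


def synth_coupled_series(
    n_epochs: int,
    lag_epochs: int = 0,
    coupling: float = 0.6,
    seed: int = 0,
    burst_period_epochs: int = 30,
    burst_len_epochs: int = 4,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-level (slope, EM amplitude) series with a known lag coupling.

    The EM amplitude series is zero outside bursts (every
    ``burst_period_epochs`` epochs) and log-normal inside them.  The slope
    series is unit-variance noise plus ``coupling`` times the standardized
    EM series shifted so that the cross-correlation convention (negative lag
    = slope leads) peaks at ``lag_epochs``.  ``coupling=0`` gives independent
    series for null calibration.
    """
    rng = np.random.default_rng(seed)
    em = np.zeros(n_epochs)
    for c in range(burst_period_epochs // 2, n_epochs, burst_period_epochs):
        j = int(c + rng.integers(-2, 3))
        for k in range(j, min(j + burst_len_epochs, n_epochs)):
            if 0 <= k:
                em[k] = 180.0 * np.exp(0.3 * rng.standard_normal())
    slope = -2.1 + noise_sd * 0.15 * rng.standard_normal(n_epochs)
    if coupling != 0.0:
        z = (em - em.mean()) / em.std() if em.std() > 0 else em
        shifted = np.zeros(n_epochs)
        if lag_epochs >= 0:
            shifted[lag_epochs:] = z[: n_epochs - lag_epochs]
        else:
            shifted[:lag_epochs] = z[-lag_epochs:]
        slope -= coupling * 0.15 * shifted  # larger EMs -> steeper slope
    return slope, em


def write_episode(
    out_dir: str | Path,
    rec: Recording,
    gt: GroundTruth,
    spec: SyntheticSpec,
    stem: str = "episode",
) -> dict[str, Path]:
    """Write a synthetic episode to EDF + ground-truth CSV + spec JSON."""
    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": out_dir / f"{stem}.edf",
        "ground_truth": out_dir / f"{stem}_ground_truth.csv",
        "spec": out_dir / f"{stem}_spec.json",
        "hypnogram": out_dir / f"{stem}_hypnogram.csv",
    }
    write_edf(paths["edf"], rec.channels, rec.sample_rate)
    peak_by_epoch = {}
    for ev in gt.em_events:
        k = int(ev.peak_time // EPOCH_S)
        peak_by_epoch[k] = max(peak_by_epoch.get(k, 0.0), ev.amplitude)
    rows = [
        {"epoch_index": k, "start_s": k * EPOCH_S, "label": lab,
         "peak_amp_uV": peak_by_epoch.get(k, 0.0)}
        for k, lab in enumerate(gt.epoch_labels)
    ]
    pd.DataFrame(rows).to_csv(paths["ground_truth"], index=False)
    pd.DataFrame({"stage": rec.hypnogram}).to_csv(paths["hypnogram"], index=False)
    paths["spec"].write_text(json.dumps(asdict(spec), indent=2))
    return paths
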