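"""Rule-based phasic/tonic classification of 4-s REM epochs from EOG.

A 4-s epoch is *phasic* when both of its 2-s subwindows contain an
eye-movement deflection (excursion above 150 uV whose above-threshold extent
is shorter than 500 ms), and *tonic* when the epoch and the immediately
flanking 2-s windows are quiescent (all excursions below 25 uV).  Everything
else is unclassified.  To avoid cross-contamination between microstates,
selected segments must additionally be at least 8 s apart; epochs dropped by
that rule are marked excluded without changing their class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "WindowFlag",
    "SegmentationConfig",
    "EpochLabel",
    "find_deflections",
    "combine_flags",
    "classify_epochs",
    "enforce_separation",
    "segment_eog",
]


class WindowFlag(str, Enum):
    EM = "EM"
    QUIESCENT = "quiescent"
    INTERMEDIATE = "intermediate"


@dataclass
class SegmentationConfig:
    """Thresholds of the binary segmentation rules (amplitudes in uV, times in s)."""

    window: float = 4.0
    subwindow: float = 2.0
    phasic_min_amplitude: float = 150.0
    phasic_max_duration: float = 0.5
    tonic_max_amplitude: float = 25.0
    min_separation: float = 8.0

    def __post_init__(self) -> None:
        if min(self.phasic_min_amplitude, self.tonic_max_amplitude) <= 0:
            raise ValueError("amplitude thresholds must be positive")
        if self.window % self.subwindow != 0:
            raise ValueError("subwindow must divide window")


@dataclass
class EpochLabel:
    epoch_index: int
    label: str  # phasic | tonic | unclassified | excluded

    @property
    def start_s(self) -> float:
        return self.epoch_index * 4.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def find_deflections(
    eog: np.ndarray, sample_rate: float, cfg: SegmentationConfig | None = None
) -> list[WindowFlag]:
    """Flag each non-overlapping 2-s window of one EOG channel.

    A window is ``EM`` if it intersects a contiguous excursion above the
    150-uV threshold shorter than 500 ms, ``quiescent`` if every sample stays
    below 25 uV, otherwise ``intermediate`` (e.g. a sustained high-amplitude
    artefact or a medium-amplitude deflection).
    """
    cfg = cfg or SegmentationConfig()
    x = np.abs(np.asarray(eog, float))
    n_win = int(len(x) // (cfg.subwindow * sample_rate))
    step = int(round(cfg.subwindow * sample_rate))
    max_run = cfg.phasic_max_duration * sample_rate

    em_windows: set[int] = set()
    sustained: set[int] = set()
    for a, b in _runs(x > cfg.phasic_min_amplitude):
        target = em_windows if (b - a) < max_run else sustained
        for w in range(a // step, min((b - 1) // step, n_win - 1) + 1):
            target.add(w)

    flags = []
    for w in range(n_win):
        if w in em_windows and w not in sustained:
            flags.append(WindowFlag.EM)
        elif x[w * step : (w + 1) * step].max() < cfg.tonic_max_amplitude:
            flags.append(WindowFlag.QUIESCENT)
        else:
            flags.append(WindowFlag.INTERMEDIATE)
    return flags


def combine_flags(
    flags_left: list[WindowFlag], flags_right: list[WindowFlag]
) -> list[WindowFlag]:
    """Merge per-channel window flags: an EM on either channel counts (the
    conjugacy of the two channels is checked upstream by the event detector,
    not re-checked here); quiescence requires both channels quiet."""
    out = []
    for fl, fr in zip(flags_left, flags_right):
        if WindowFlag.EM in (fl, fr):
            out.append(WindowFlag.EM)
        elif fl == fr == WindowFlag.QUIESCENT:
            out.append(WindowFlag.QUIESCENT)
        else:
            out.append(WindowFlag.INTERMEDIATE)
    return out


def classify_epochs(
    window_flags: list[WindowFlag], cfg: SegmentationConfig | None = None
) -> list[EpochLabel]:
    """Label 4-s epochs phasic/tonic/unclassified from 2-s window flags.

    Phasic requires EM flags in both subwindows (two consecutive EMs in
    adjacent 2-s windows); tonic requires the epoch's subwindows *and* the
    flanking 2-s windows to be quiescent.  Windows beyond the signal edge
    count as quiescent.
    """
    cfg = cfg or SegmentationConfig()
    n_epochs = len(window_flags) // 2
    q = WindowFlag.QUIESCENT

    def flag(w: int) -> WindowFlag:
        return window_flags[w] if 0 <= w < len(window_flags) else q

    labels = []
    for k in range(n_epochs):
        w0, w1 = 2 * k, 2 * k + 1
        if window_flags[w0] == window_flags[w1] == WindowFlag.EM:
            lab = "phasic"
        elif all(flag(w) == q for w in (w0 - 1, w0, w1, w1 + 1)):
            lab = "tonic"
        else:
            lab = "unclassified"
        labels.append(EpochLabel(epoch_index=k, label=lab))
    return labels


def enforce_separation(
    labels: list[EpochLabel], cfg: SegmentationConfig | None = None
) -> list[EpochLabel]:
    """Greedy earliest-first selection keeping segments >= 8 s apart.

    A phasic or tonic epoch is kept only if its start is at least
    ``min_separation`` after the end of the previously kept epoch; dropped
    candidates become ``excluded``.  Unclassified epochs are untouched.
    """
    cfg = cfg or SegmentationConfig()
    out = []
    last_end = -np.inf
    for lab in sorted(labels, key=lambda l: l.epoch_index):
        if lab.label in ("phasic", "tonic"):
            start = lab.epoch_index * cfg.window
            if start - last_end >= cfg.min_separation - 1e-9:
                out.append(EpochLabel(lab.epoch_index, lab.label))
                last_end = start + cfg.window
            else:
                out.append(EpochLabel(lab.epoch_index, "excluded"))
        else:
            out.append(EpochLabel(lab.epoch_index, lab.label))
    return out


def segment_eog(
    loc: np.ndarray,
    roc: np.ndarray,
    sample_rate: float,
    cfg: SegmentationConfig | None = None,
) -> tuple[list[EpochLabel], list[EpochLabel]]:
    """Full segmentation of a bilateral EOG pair.

    Returns ``(labels, kept)`` where ``labels`` are the raw class labels and
    ``kept`` additionally applies the 8-s separation rule.
    """
    cfg = cfg or SegmentationConfig()
    flags = combine_flags(
        find_deflections(loc, sample_rate, cfg),
        find_deflections(roc, sample_rate, cfg),
    )
    labels = classify_epochs(flags, cfg)
    return labels, enforce_separation(labels, cfg)
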