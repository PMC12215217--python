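"""Polysomnography recording container shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard 10-20 channel sets averaged into each topographical area.
AREA_CHANNELS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fz", "F3", "F4"),
    "central": ("Cz", "C3", "C4"),
    "parietal": ("Pz", "P3", "P4"),
    "occipital": ("O1", "O2"),
}

#: Bilateral electrooculogram channel labels (left / right outer canthus).
EOG_CHANNELS: tuple[str, str] = ("LOC", "ROC")

#: Sleep-stage scoring epoch length in seconds (AASM).
SCORING_EPOCH_S: float = 30.0


@dataclass
class Recording:
    """Multichannel EEG/EOG signal block with hypnogram and montage metadata.

    Parameters
    ----------
    channels
        Map of channel label to signal in microvolts. All channels must have
        the same length and sample rate.
    sample_rate
        Sampling frequency in Hz, shared by all channels.
    hypnogram
        Sleep stage per 30-s scoring epoch (e.g. ``"R"``, ``"N2"``, ``"W"``).
    area_map
        Map of topographical area name to the channel labels averaged into it.
    metadata
        Free-form descriptors (participant id, reference montage, ...).
    """

    channels: dict[str, np.ndarray]
    sample_rate: float
    hypnogram: np.ndarray
    area_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(AREA_CHANNELS)
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(np.asarray(v)) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.hypnogram = np.asarray(self.hypnogram)
        if self.channels:
            dur = self.n_samples / self.sample_rate
            hyp_dur = len(self.hypnogram) * SCORING_EPOCH_S
            if abs(dur - hyp_dur) > SCORING_EPOCH_S:
                raise ValueError(
                    f"hypnogram spans {hyp_dur:.0f} s but signal spans "
                    f"{dur:.0f} s (mismatch exceeds one scoring epoch)"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n_samples / self.sample_rate

    def eog_pair(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the (left, right) EOG channel samples."""
        loc, roc = EOG_CHANNELS
        for label in (loc, roc):
            if label not in self.channels:
                raise KeyError(f"EOG channel {label!r} not present in recording")
        return self.channels[loc], self.channels[roc]
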