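"""End-to-end orchestration: I/O, configuration and the two analysis arms.

The *binary* arm segments REM into phasic and tonic 4-s epochs from EOG,
fits per-epoch aperiodic slopes per area and band, and runs the group
statistics (paired contrasts, ROC, multiplicity adjustment).  The
*within-episode* arm selects REM episodes longer than 10 min, builds the
continuous eye-movement amplitude and slope series on the shared 4-s grid,
and runs the lagged cross-correlation, episode-centred effect sizes and
Bayesian prevalence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, oculomotor, segmentation, spectral, temporal
from .recording import AREA_CHANNELS, SCORING_EPOCH_S, Recording

__all__ = [
    "Recording",
    "RunConfig",
    "read_recording",
    "run_binary_analysis",
    "run_within_episode_analysis",
]

logger = logging.getLogger("remaperiodic")

EPOCH_S = spectral.EPOCH_S


@dataclass
class RunConfig:
    """Serializable bundle of all stage configurations."""

    irasa: spectral.IrasaConfig = field(default_factory=spectral.IrasaConfig)
    segmentation: segmentation.SegmentationConfig = field(
        default_factory=segmentation.SegmentationConfig
    )
    em_detect: oculomotor.EMDetectConfig = field(
        default_factory=oculomotor.EMDetectConfig
    )
    min_episode_s: float = temporal.MIN_EPISODE_S
    zscore_level: str = "epoch"  # "epoch" | "mean"
    ci_n: str = "overlap"  # per-lag CI length mode: "overlap" | "full"
    fdr_q: float = 0.05
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["irasa"]["hset"] = list(d["irasa"]["hset"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "irasa" in d:
            irasa = dict(d["irasa"])
            if "hset" in irasa:
                irasa["hset"] = tuple(irasa["hset"])
            for key in ("band_low", "band_low_control", "band_high"):
                if key in irasa:
                    irasa[key] = tuple(irasa[key])
            d["irasa"] = spectral.IrasaConfig(**irasa)
        if "segmentation" in d:
            d["segmentation"] = segmentation.SegmentationConfig(**d["segmentation"])
        if "em_detect" in d:
            em = dict(d["em_detect"])
            for key in ("band", "duration_bounds", "freq_bounds"):
                if key in em:
                    em[key] = tuple(em[key])
            d["em_detect"] = oculomotor.EMDetectConfig(**em)
        return cls(**d)


def read_recording(
    edf_path: str | Path,
    hypnogram_path: str | Path,
    area_map: dict[str, tuple[str, ...]] | None = None,
    participant: str | None = None,
) -> Recording:
    """Load an EDF file plus hypnogram CSV into a :class:`Recording`.

    Signals are converted to microvolts.  Channels named in ``area_map``
    must be present; a missing channel raises an error naming it.  No
    resampling or re-referencing is performed.
    """
    import mne

    area_map = dict(area_map or AREA_CHANNELS)
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    needed = [lb for labels in area_map.values() for lb in labels]
    missing = [lb for lb in needed if lb not in channels]
    if missing:
        raise KeyError(f"EDF file lacks channel(s) {missing} required by area_map")
    hyp = pd.read_csv(hypnogram_path)["stage"].to_numpy()
    return Recording(
        channels=channels,
        sample_rate=float(raw.info["sfreq"]),
        hypnogram=hyp,
        area_map=area_map,
        metadata={"participant": participant or Path(edf_path).stem,
                  "source": str(edf_path)},
    )


def _slope_table(
    rec: Recording, cfg: RunConfig, epoch_indices=None
) -> pd.DataFrame:
    areas = spectral.average_area_signal(rec.channels, rec.sample_rate, rec.area_map)
    return spectral.epoch_slopes(areas, cfg.irasa, epoch_indices=epoch_indices)


def run_binary_analysis(
    recordings: list[Recording], cfg: RunConfig | None = None
) -> dict:
    """Binary phasic/tonic pipeline over a cohort of recordings.

    Segments each recording's EOG, fits per-epoch slopes for the kept
    phasic/tonic epochs, z-transforms within participant, and returns the
    participant summaries, paired contrasts (with BH adjustment over the
    area-by-band family), and ROC results.  Participants with zero kept
    epochs of either state are dropped with a logged reason.
    """
    cfg = cfg or RunConfig()
    if len(recordings) < 3:
        raise ValueError("group statistics require at least 3 recordings")
    epoch_rows = []
    exclusions = []
    for rec in recordings:
        participant = rec.metadata.get("participant", "unknown")
        loc, roc = rec.eog_pair()
        _, kept = segmentation.segment_eog(loc, roc, rec.sample_rate, cfg.segmentation)
        state = {l.epoch_index: l.label for l in kept if l.label in ("phasic", "tonic")}
        counts = pd.Series([l.label for l in kept]).value_counts()
        logger.info("participant %s kept epochs: %s", participant, counts.to_dict())
        if not {"phasic", "tonic"} <= set(state.values()):
            exclusions.append({"participant": participant,
                               "reason": "missing_state_epochs"})
            logger.warning("dropping %s: no kept epochs of one state", participant)
            continue
        slopes = _slope_table(rec, cfg, epoch_indices=sorted(state))
        slopes = slopes.assign(
            participant=participant,
            state=slopes.epoch_index.map(state),
        )
        epoch_rows.append(slopes)
    if not epoch_rows:
        return {"status": "no participants with both states", "summaries": None}
    epochs = pd.concat(epoch_rows, ignore_index=True)
    summaries = cohort.participant_summaries(epochs, level=cfg.zscore_level)

    contrasts = []
    rocs = []
    wide = summaries.pivot_table(
        index=["participant", "area", "band"], columns="state", values="mean_z"
    ).reset_index()
    for (area, band), grp in wide.groupby(["area", "band"]):
        grp = grp.dropna(subset=["phasic", "tonic"])
        res = cohort.paired_contrast(grp["phasic"], grp["tonic"], area=area, band=band)
        contrasts.append(res.__dict__)
        roc = cohort.auc_mann_whitney(grp["phasic"], grp["tonic"], area=area, band=band)
        rocs.append(roc.__dict__)
    contrasts = pd.DataFrame(contrasts)
    reject, p_adj = cohort.bh_adjust(contrasts["p"], q=cfg.fdr_q)
    contrasts["p_adj"] = p_adj
    contrasts["significant"] = reject
    return {
        "status": "ok",
        "epochs": epochs,
        "summaries": summaries,
        "contrasts": contrasts,
        "roc": pd.DataFrame(rocs),
        "exclusions": pd.DataFrame(exclusions),
    }


def run_within_episode_analysis(
    recordings: list[Recording], cfg: RunConfig | None = None
) -> dict:
    """Within-episode continuous pipeline over one or more recordings.

    For every REM episode longer than the minimum duration, builds the
    epoch-level EM amplitude and slope series, cross-correlates them per
    area and band, pools Fisher z across episodes, and estimates
    episode-centred effect sizes and Bayesian prevalence at lag 0 (negative
    correlations for the low band, positive for the high band).
    """
    cfg = cfg or RunConfig()
    results: dict[tuple[str, str], list[temporal.CrossCorrResult]] = {}
    episode_meta = []
    for rec in recordings:
        participant = rec.metadata.get("participant", "unknown")
        episodes = temporal.select_episodes(
            rec.hypnogram, cfg.min_episode_s, SCORING_EPOCH_S
        )
        if not episodes:
            episode_meta.append({"participant": participant, "episodes": 0,
                                 "reason": f"no episodes > {cfg.min_episode_s:.0f} s"})
            continue
        loc, roc = rec.eog_pair()
        events = oculomotor.detect_rem_events(loc, roc, rec.sample_rate, cfg.em_detect)
        slopes = _slope_table(rec, cfg)
        for start, end in episodes:
            k0 = int(start // EPOCH_S)
            n_ep = int((end - start) // EPOCH_S)
            n_total = int(rec.duration // EPOCH_S)
            n_ep = min(n_ep, n_total - k0)
            amp_all = oculomotor.epoch_amplitude_series(events, n_total)
            amp = amp_all[k0 : k0 + n_ep]
            for (area, band), grp in slopes.groupby(["area", "band"]):
                series = (
                    grp.set_index("epoch_index")["slope"]
                    .reindex(range(k0, k0 + n_ep))
                    .to_numpy()
                )
                good = np.isfinite(series)
                if good.sum() <= 10:
                    continue
                if not good.all():  # fill isolated failures with the median
                    series = np.where(good, series, np.nanmedian(series))
                res = temporal.cross_correlate(series, amp, ci_n=cfg.ci_n)
                results.setdefault((area, band), []).append(res)
            episode_meta.append({"participant": participant, "start_s": start,
                                 "end_s": end, "n_epochs": n_ep})
    if not results:
        return {"status": "no episodes > 10 min", "episodes": pd.DataFrame(episode_meta)}

    pooled = {}
    effect = []
    for (area, band), res_list in results.items():
        pooled[(area, band)] = temporal.pool_episode_correlations(res_list)
        sign = "negative" if band == "low" else "positive"
        prop = temporal.episode_effect_size(res_list, sign=sign)
        k = round(prop * len(res_list))
        prev = temporal.bayesian_prevalence(k, len(res_list), alpha=cfg.alpha)
        effect.append({"area": area, "band": band, "sign": sign,
                       "k": k, "n_episodes": len(res_list), "proportion": prop,
                       "prevalence_map": prev.map_estimate,
                       "hpdi_lo": prev.hpdi[0], "hpdi_hi": prev.hpdi[1]})
    logger.info("analysed %d episode series groups", len(results))
    return {
        "status": "ok",
        "xcorr": results,
        "pooled": pooled,
        "effect_sizes": pd.DataFrame(effect),
        "episodes": pd.DataFrame(episode_meta),
    }


def save_results(out_dir: str | Path, results: dict) -> None:
    """Write analysis result tables to CSV/JSON under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out_dir / f"{key}.csv", index=False)
        elif isinstance(val, str):
            (out_dir / "status.json").write_text(json.dumps({"status": val}))
        elif key == "pooled":
            rows = []
            for (area, band), p in val.items():
                for lag, z, r in zip(p["lags"], p["mean_z"], p["r"]):
                    rows.append({"area": area, "band": band, "lag_s": lag,
                                 "mean_z": z, "r": r})
            pd.DataFrame(rows).to_csv(out_dir / "pooled_xcorr.csv", index=False)
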