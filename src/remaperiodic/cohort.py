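"""Between-state group statistics for the binary phasic/tonic analysis.

Per participant, epoch-level aperiodic slopes from the four topographical
areas and both states are pooled into one vector and z-transformed (so that
device- or subject-specific offsets cancel before pooling across
recordings), then averaged per (area, state).  Paired contrasts (Student's
t, Cohen's d on difference scores, tonic minus phasic), ROC/AUC with a
pooled-median cutoff, Benjamini-Hochberg adjustment, and the pooled-epoch
Spearman correlation between eye-movement amplitude and slope complete the
statistical surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastResult",
    "RocResult",
    "zscore_within_participant",
    "participant_summaries",
    "paired_contrast",
    "auc_mann_whitney",
    "bh_adjust",
    "epoch_amplitude_correlation",
]


@dataclass
class ContrastResult:
    """Paired t-test of tonic vs phasic mean slopes across participants."""

    area: str
    band: str
    t: float
    p: float
    d: float  # Cohen's d on difference scores, sign of mean(tonic - phasic)
    n: int


@dataclass
class RocResult:
    """Discriminability of the two states from slope values."""

    area: str
    band: str
    auc: float
    auc_se: float
    sensitivity: float
    specificity: float
    cutoff: float


def zscore_within_participant(values: np.ndarray) -> np.ndarray:
    """Z-transform of one participant's pooled slope vector (ddof=1)."""
    x = np.asarray(values, float)
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 2:
        raise ValueError("zero variance: cannot z-transform")
    mu = finite.mean()
    sd = finite.std(ddof=1)
    return (x - mu) / sd


def participant_summaries(epochs: pd.DataFrame, level: str = "epoch") -> pd.DataFrame:
    """Per-participant mean slope (raw and z-scored) per area, band and state.

    ``epochs`` is tidy with columns ``participant, area, band, state, slope``
    (one row per kept epoch).  The z-transform pools all of a participant's
    epoch-level slopes of one band across areas and states (``level="epoch"``)
    or pools the eight (area, state) means (``level="mean"``), then averages
    per cell.
    """
    if level not in ("epoch", "mean"):
        raise ValueError("level must be 'epoch' or 'mean'")
    out = []
    for (participant, band), grp in epochs.groupby(["participant", "band"]):
        grp = grp.dropna(subset=["slope"])
        if level == "epoch":
            z = zscore_within_participant(grp["slope"].to_numpy())
            grp = grp.assign(z=z)
            cell = grp.groupby(["area", "state"]).agg(
                mean_slope=("slope", "mean"), mean_z=("z", "mean")
            )
        else:
            means = grp.groupby(["area", "state"])["slope"].mean()
            z = zscore_within_participant(means.to_numpy())
            cell = means.to_frame("mean_slope").assign(mean_z=z)
        for (area, state), row in cell.iterrows():
            out.append(
                {
                    "participant": participant,
                    "area": area,
                    "band": band,
                    "state": state,
                    "mean_slope": row["mean_slope"],
                    "mean_z": row["mean_z"],
                }
            )
    return pd.DataFrame(out)


def paired_contrast(
    phasic: np.ndarray, tonic: np.ndarray, area: str = "", band: str = ""
) -> ContrastResult:
    """Two-tailed paired Student's t and Cohen's d on tonic - phasic scores.

    With the (negative) slope convention, a positive d means the tonic state
    is *flatter* (less negative) than phasic; high-band d values are
    negative when phasic is flatter.
    """
    phasic = np.asarray(phasic, float)
    tonic = np.asarray(tonic, float)
    if phasic.shape != tonic.shape:
        raise ValueError("unpaired inputs")
    if phasic.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = tonic - phasic
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return ContrastResult(area, band, 0.0, 1.0, 0.0, diff.size)
        raise ValueError("zero-variance non-zero differences")
    t, p = stats.ttest_rel(tonic, phasic)
    d = diff.mean() / sd
    return ContrastResult(area=area, band=band, t=float(t), p=float(p),
                          d=float(d), n=diff.size)


def auc_mann_whitney(
    phasic: np.ndarray, tonic: np.ndarray, area: str = "", band: str = ""
) -> RocResult:
    """AUC via the Mann-Whitney rank identity, with a pooled-median cutoff.

    The class with the larger mean is the "positive" one; AUC is the
    probability that a positive-class value ranks above a negative-class
    value (ties half credit).  Sensitivity/specificity are evaluated at the
    median of all pooled values.  The standard error follows Hanley &
    McNeil and is reported for description only.
    """
    phasic = np.asarray(phasic, float)
    tonic = np.asarray(tonic, float)
    if phasic.size == 0 or tonic.size == 0:
        raise ValueError("both groups must be non-empty")
    if phasic.mean() >= tonic.mean():
        pos, neg = phasic, tonic
    else:
        pos, neg = tonic, phasic
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)
    cutoff = float(np.median(np.concatenate([phasic, tonic])))
    sens = float(np.mean(pos > cutoff))
    spec = float(np.mean(neg <= cutoff))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    n1, n2 = pos.size, neg.size
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    return RocResult(area=area, band=band, auc=auc, auc_se=float(np.sqrt(max(var, 0.0))),
                     sensitivity=sens, specificity=spec, cutoff=cutoff)


def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (reject flags, adjusted p-values) at false discovery rate ``q``.
    """
    pvals = np.asarray(pvals, float)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def epoch_amplitude_correlation(
    epochs: pd.DataFrame,
    min_amplitude: float = 50.0,
    min_epochs: int = 10,
) -> pd.DataFrame:
    """Pooled-epoch Spearman correlation of EM amplitude with slope.

    ``epochs`` is tidy with columns ``area, band, em_amplitude, slope``; only
    epochs containing an EM event (amplitude above ``min_amplitude``) enter.
    Returns one row per (area, band) with Spearman r and p.
    """
    sel = epochs[epochs["em_amplitude"] > min_amplitude].dropna(subset=["slope"])
    out = []
    for (area, band), grp in sel.groupby(["area", "band"]):
        if len(grp) < min_epochs:
            raise ValueError(
                f"only {len(grp)} epochs with EM events for ({area}, {band}); "
                f"need at least {min_epochs}"
            )
        r, p = stats.spearmanr(grp["em_amplitude"], grp["slope"])
        out.append({"area": area, "band": band, "r": float(r), "p": float(p),
                    "n": len(grp)})
    return pd.DataFrame(out)
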