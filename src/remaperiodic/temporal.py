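"""Within-episode temporal analysis of eye movements and aperiodic slopes.

For each REM episode longer than 10 min, the per-epoch eye-movement
amplitude series is cross-correlated with the per-epoch aperiodic slope
series at lags of -5 to +5 min in 4-s steps.  Both series are rank
transformed once (mid-ranks for ties), correlated with Pearson's formula on
the overlapping segments (Spearman correlation at lag 0), Fisher
z-transformed, and tested per lag against a confidence interval based on
the overlap length.  Episode-centred effect sizes (the fraction of episodes
with a significant correlation) feed a Bayesian estimate of the population
prevalence of the effect.

Sign convention (matching the pooled cross-correlation figures of
phasic/tonic studies): a negative lag means the slope series leads the eye
movement series; a positive lag means it lags behind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Episode",
    "CrossCorrResult",
    "PrevalenceEstimate",
    "select_episodes",
    "rank_with_ties",
    "cross_correlate",
    "pool_episode_correlations",
    "episode_effect_size",
    "bayesian_prevalence",
]

EPOCH_S = 4.0

#: Minimum REM episode duration for within-episode analysis (s): episodes
#: must span several ~2-min infra-slow EM burst cycles.
MIN_EPISODE_S = 600.0


@dataclass
class Episode:
    """One REM episode's aligned epoch-level series."""

    participant: str
    start: float  # s
    end: float  # s
    slope_series: dict  # (area, band) -> np.ndarray of slope per epoch
    em_amplitude: np.ndarray  # uV per epoch

    @property
    def n_epochs(self) -> int:
        return len(self.em_amplitude)


@dataclass
class CrossCorrResult:
    """Per-lag ranked cross-correlation for one episode/area/band."""

    lags: np.ndarray  # s
    r: np.ndarray
    z: np.ndarray  # Fisher z = atanh(r)
    ci_halfwidth: np.ndarray  # on the r scale
    significant: np.ndarray  # boolean
    n: int  # series length in epochs


@dataclass
class PrevalenceEstimate:
    """Posterior summary of the population prevalence of a within-unit effect."""

    k: int
    n: int
    alpha: float
    map_estimate: float
    hpdi: tuple[float, float]
    hpdi_level: float = 0.96


def select_episodes(
    hypnogram: np.ndarray,
    min_duration: float = MIN_EPISODE_S,
    stage_duration: float = 30.0,
    rem_stage: str = "R",
) -> list[tuple[float, float]]:
    """Maximal contiguous REM runs longer than ``min_duration`` seconds.

    Returns (start_s, end_s) pairs.  Runs of exactly ``min_duration`` are
    excluded ("longer than").  Episode boundaries are strict: a single
    non-REM scoring epoch splits a run.
    """
    hyp = np.asarray(hypnogram)
    if hyp.size == 0:
        raise ValueError("empty hypnogram")
    mask = hyp == rem_stage
    out = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j < mask.size and mask[j]:
                j += 1
            start, end = i * stage_duration, j * stage_duration
            if end - start > min_duration:
                out.append((start, end))
            i = j
        else:
            i += 1
    return out


def rank_with_ties(x: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..n with mid-ranks for ties."""
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return stats.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_correlate(
    slope_series: np.ndarray,
    em_series: np.ndarray,
    max_lag: float = 300.0,
    step: float = EPOCH_S,
    ci_level: float = 0.95,
    ci_n: str = "overlap",
    min_overlap: int = 5,
) -> CrossCorrResult:
    """Ranked lagged cross-correlation between slope and EM amplitude series.

    Both series are rank transformed once over their full length; at lag
    ``l = k*step`` the correlation pairs ``slope[t]`` with ``em[t - k]``
    over the overlapping ``n - |k|`` epochs (truncation, no wraparound).
    The per-lag CI half-width is ``z_crit / sqrt(n_l - 3)`` on the Fisher-z
    scale mapped back through tanh, with ``n_l`` the overlap length
    (``ci_n="overlap"``) or the full series length (``ci_n="full"``).
    Lags with overlap of fewer than ``min_overlap`` epochs are NaN.
    """
    slope_series = np.asarray(slope_series, float)
    em_series = np.asarray(em_series, float)
    if slope_series.shape != em_series.shape:
        raise ValueError("series must have equal length")
    n = slope_series.size
    if n <= 10:
        raise ValueError("series too short for lagged cross-correlation (n <= 10)")

    rs = rank_with_ties(slope_series)
    re = rank_with_ties(em_series)
    k_max = int(round(max_lag / step))
    ks = np.arange(-k_max, k_max + 1)
    r = np.full(ks.size, np.nan)
    n_l = n - np.abs(ks)
    for idx, k in enumerate(ks):
        if n_l[idx] < min_overlap:
            continue
        if k >= 0:
            a, b = rs[k:], re[: n - k]
        else:
            a, b = rs[: n + k], re[-k:]
        r[idx] = _pearson(a, b)

    z_crit = stats.norm.ppf(0.5 + ci_level / 2)
    n_ci = n_l if ci_n == "overlap" else np.full(ks.size, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.tanh(z_crit / np.sqrt(np.maximum(n_ci - 3, 0)))
        ci[n_ci <= 3] = np.nan
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    sig = np.abs(r) > ci
    sig &= np.isfinite(r)
    return CrossCorrResult(
        lags=ks * step, r=r, z=z, ci_halfwidth=ci, significant=sig, n=n
    )


def pool_episode_correlations(
    results: list[CrossCorrResult],
) -> dict[str, np.ndarray]:
    """Average Fisher z per lag across episodes.

    Returns lags, the mean z, its back-transform ``r = tanh(mean z)`` and
    the standard deviation of z across episodes.
    """
    if not results:
        raise ValueError("no episodes to pool")
    lags = results[0].lags
    for res in results:
        if not np.array_equal(res.lags, lags):
            raise ValueError("episodes have mismatching lag grids")
    zs = np.stack([res.z for res in results])
    import warnings as _warnings

    with _warnings.catch_warnings():
        # lags with no valid overlap in any episode stay NaN
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_z = np.nanmean(zs, axis=0)
        sd_z = np.nanstd(zs, axis=0, ddof=1) if len(results) > 1 else np.zeros_like(mean_z)
    return {"lags": lags, "mean_z": mean_z, "r": np.tanh(mean_z), "sd_z": sd_z}


def episode_effect_size(
    results: list[CrossCorrResult],
    lag_window: tuple[float, float] = (0.0, 0.0),
    sign: str | None = None,
) -> float:
    """Fraction of episodes with a significant correlation in ``lag_window``.

    ``sign`` restricts counting to "negative" or "positive" correlations
    (the direction hypothesised for the low and high band respectively);
    ``None`` counts either.
    """
    if not results:
        return 0.0
    lo, hi = lag_window
    count = 0
    for res in results:
        in_win = (res.lags >= lo - 1e-9) & (res.lags <= hi + 1e-9)
        if not in_win.any():
            raise ValueError(f"lag window {lag_window} outside computed lags")
        sig = res.significant[in_win]
        rr = res.r[in_win]
        if sign == "negative":
            sig = sig & (rr < 0)
        elif sign == "positive":
            sig = sig & (rr > 0)
        count += bool(sig.any())
    return count / len(results)


def bayesian_prevalence(
    k: int,
    n: int,
    alpha: float = 0.05,
    hpdi_level: float = 0.96,
    grid_step: float = 5e-4,
) -> PrevalenceEstimate:
    """Posterior over the population prevalence of a within-episode effect.

    Each episode yields a significant test with probability
    ``theta = gamma + (1 - gamma) * alpha`` where ``gamma`` is the
    prevalence of true effects (within-episode sensitivity taken as 1) and
    ``alpha`` the false-positive rate.  With a uniform prior on ``gamma``
    the posterior density on a gamma grid is the binomial likelihood of
    ``k`` of ``n`` at ``theta(gamma)``; the MAP and the highest-density
    interval at ``hpdi_level`` are read off the grid.  The continuous MAP
    has the closed form ``max(0, (k/n - alpha) / (1 - alpha))``.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < alpha < 1:
        raise ValueError("need 0 < alpha < 1")
    from scipy.special import xlogy

    gamma = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    theta = gamma + (1 - gamma) * alpha
    log_post = xlogy(k, theta) + xlogy(n - k, 1 - theta)  # xlogy(0, 0) == 0
    post = np.exp(log_post - log_post.max())
    post /= post.sum()
    map_idx = int(np.argmax(post))

    order = np.argsort(post)[::-1]
    mass = np.cumsum(post[order])
    included = order[: int(np.searchsorted(mass, hpdi_level)) + 1]
    hpdi = (float(gamma[included].min()), float(gamma[included].max()))
    return PrevalenceEstimate(
        k=k, n=n, alpha=alpha, map_estimate=float(gamma[map_idx]),
        hpdi=hpdi, hpdi_level=hpdi_level,
    )
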