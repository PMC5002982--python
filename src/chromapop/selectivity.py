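"""Selectivity, sparseness, and the warm/cool tuning-bias test.

Narrowness summaries computed on raw mean firing rates to the
low-luminance and high-luminance hue-matched stimulus subsets:

* selectivity index = 1 - min(response) / max(response), in [0, 1];
* sparseness index = [1 - (sum r_i / n)^2 / (sum r_i^2 / n)] / (1 - 1/n),
  which is 1 for a one-hot response profile and 0 for a flat one.

A cell is *excluded* when neither luminance set yields selectivity
above 0.6, *sharply selective* when any retained set has sparseness
above 0.3, and *broadly selective* otherwise (strict inequalities at
both gates).

The warm/cool permutation test asks whether a population's peak hue
angles over-represent warm hues (pink through yellow) relative to cool
hues (green through violet): the observed warm:cool ratio is compared
with a null in which every cell is assigned one of the 45 stimulus hue
angles uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import wrap360
from .config import DEFAULT_COOL_ARC, DEFAULT_WARM_ARC

SELECTIVITY_GATE = 0.6
SPARSENESS_GATE = 0.3


@dataclass
class SelectivitySummary:
    neuron_id: str
    selectivity_low: float
    selectivity_high: float
    sparseness_low: float
    sparseness_high: float
    category: str                   # "sharp" | "broad" | "excluded"


def selectivity_index(responses) -> float:
    """1 - min/max over raw (nonnegative) mean rates."""
    r = np.asarray(responses, dtype=float)
    if np.any(r < 0):
        raise ValueError("selectivity index requires nonnegative rates")
    mx = r.max()
    if mx <= 0:
        raise ValueError("selectivity index undefined for all-zero responses")
    return float(1.0 - r.min() / mx)


def sparseness_index(responses) -> float:
    """Normalized response concentration across stimuli."""
    r = np.asarray(responses, dtype=float)
    n = r.size
    if np.any(r < 0):
        raise ValueError("sparseness index requires nonnegative rates")
    sum_sq = np.sum(r ** 2)
    if sum_sq <= 0:
        raise ValueError("sparseness index undefined for all-zero responses")
    num = 1.0 - (np.sum(r) / n) ** 2 / (sum_sq / n)
    return float(num / (1.0 - 1.0 / n))


def classify_sharp_broad(selectivity_low, selectivity_high,
                         sparseness_low, sparseness_high,
                         selectivity_gate: float = SELECTIVITY_GATE,
                         sparseness_gate: float = SPARSENESS_GATE) -> str:
    if not (selectivity_low > selectivity_gate
            or selectivity_high > selectivity_gate):
        return "excluded"
    if sparseness_low > sparseness_gate or sparseness_high > sparseness_gate:
        return "sharp"
    return "broad"


def summarize_population(rates_low, rates_high, neuron_ids=None):
    """Per-neuron selectivity/sparseness/category over the hue-matched
    low- and high-luminance subsets (rows: neurons)."""
    rates_low = np.asarray(rates_low, dtype=float)
    rates_high = np.asarray(rates_high, dtype=float)
    out = []
    for i in range(rates_low.shape[0]):
        sel_l = selectivity_index(rates_low[i])
        sel_h = selectivity_index(rates_high[i])
        spa_l = sparseness_index(rates_low[i])
        spa_h = sparseness_index(rates_high[i])
        out.append(SelectivitySummary(
            neuron_id=(neuron_ids[i] if neuron_ids is not None else str(i)),
            selectivity_low=sel_l, selectivity_high=sel_h,
            sparseness_low=spa_l, sparseness_high=spa_h,
            category=classify_sharp_broad(sel_l, sel_h, spa_l, spa_h),
        ))
    return out


def _in_arc(angles, arc) -> np.ndarray:
    """Membership of angles in a circular arc (start -> end, ccw)."""
    a = wrap360(np.asarray(angles, dtype=float))
    start, end = wrap360(arc[0]), wrap360(arc[1])
    if start <= end:
        return (a >= start) & (a <= end)
    return (a >= start) | (a <= end)


def warm_cool_counts(peak_angles, warm_arc=DEFAULT_WARM_ARC,
                     cool_arc=DEFAULT_COOL_ARC):
    warm = int(np.sum(_in_arc(peak_angles, warm_arc)))
    cool = int(np.sum(_in_arc(peak_angles, cool_arc)))
    return warm, cool


def warm_cool_test(peak_angles, stimulus_angles, warm_arc=DEFAULT_WARM_ARC,
                   cool_arc=DEFAULT_COOL_ARC, n_perm: int = 2000,
                   n_boot: int = 2000, boot_fraction: float = 0.9,
                   seed: int = 0):
    """Permutation test of warm-over-cool tuning bias.

    Null populations assign each cell one of the ``stimulus_angles``
    uniformly at random; the statistic is the warm:cool count ratio
    (warm counts alone when a cool count of zero makes the ratio
    infinite). For each of ``n_boot`` bootstraps of ``boot_fraction`` of
    the cells, p = fraction of null populations with a ratio at least
    the bootstrap's; the reported p is the mean over bootstraps with a
    percentile 95% CI, floored at 1/n_perm.

    Returns (p_mean, (lo, hi), observed_ratio).
    """
    peaks = np.asarray(peak_angles, dtype=float)
    stim = np.asarray(stimulus_angles, dtype=float)
    n = peaks.size
    rng = np.random.default_rng(seed)

    warm_obs, cool_obs = warm_cool_counts(peaks, warm_arc, cool_arc)
    ratio_obs = warm_obs / cool_obs if cool_obs else np.inf

    null_peaks = stim[rng.integers(0, stim.size, size=(n_perm, n))]
    null_warm = _in_arc(null_peaks, warm_arc).sum(axis=1)
    null_cool = _in_arc(null_peaks, cool_arc).sum(axis=1)
    with np.errstate(divide="ignore"):
        null_ratio = np.where(null_cool > 0, null_warm / np.maximum(null_cool, 1),
                              np.inf)

    k = max(2, int(round(boot_fraction * n)))
    ps = np.empty(n_boot)
    floor = 1.0 / n_perm
    for i in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        w, c = warm_cool_counts(peaks[idx], warm_arc, cool_arc)
        if c > 0:
            p = np.mean(null_ratio >= w / c)
        else:
            # infinite observed ratio: fall back to comparing warm counts
            p = np.mean((null_cool == 0) & (null_warm >= w))
        ps[i] = max(p, floor)
    lo, hi = np.percentile(ps, [2.5, 97.5])
    return float(np.mean(ps)), (float(lo), float(hi)), float(ratio_obs)
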