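"""Luminance discrimination and cross-luminance tuning stability.

Per-cell luminance sensitivity is quantified by the area under the ROC
curve (AUC) comparing the cell's responses to two luminance classes.
The AUC is computed through the rank (Mann-Whitney U) identity — the
normalized U statistic equals the criterion-sweeping ROC area, with ties
counted one half. Significance comes from a label-shuffling permutation
test: a cell is significant at p < 0.05 when its AUC falls outside the
2.5-97.5 percentile band of the shuffled-label null.

Cross-luminance tuning stability is measured on the circle: a peak from
one class is first unwrapped next to the matching peak from the other
class, then ordinary Pearson correlations, Fisher-z comparisons and
per-hue-bin Mann-Whitney shift tests are applied to the aligned values.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from ._angles import circ_diff, unwrap_near

Z_CAP = 10.0  # atanh cap for |r| -> 1


@dataclass
class AUCResult:
    neuron_id: str
    comparison: str              # "equi_vs_low" | "high_vs_equi"
    auc: float
    p_perm: float
    significant: bool


def roc_auc(responses_a, responses_b) -> float:
    """AUC for discriminating class b from class a.

    0.5 is chance; > 0.5 means class b tends to evoke larger responses.
    Equals the Mann-Whitney U statistic over n_a * n_b with ties = 1/2.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both response sets must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_b = ranks[a.size:].sum() - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def _auc_many(pooled: np.ndarray, n_a: int) -> np.ndarray:
    """Row-wise AUC of pooled[:, n_a:] vs pooled[:, :n_a]."""
    ranks = stats.rankdata(pooled, axis=1)
    n_b = pooled.shape[1] - n_a
    u_b = ranks[:, n_a:].sum(axis=1) - n_b * (n_b + 1) / 2.0
    return u_b / (n_a * n_b)


def auc_permutation_test(responses_a, responses_b, n_perm: int = 2000,
                         seed: int = 0):
    """Two-sided permutation test of AUC against chance.

    Shuffles the luminance labels ``n_perm`` times. Returns
    (auc, p, (lo, hi)) where (lo, hi) is the null's 95% band; the AUC is
    significant at p < 0.05 when it falls outside the band. p is the
    add-one two-sided permutation p-value.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    observed = roc_auc(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(pooled, (n_perm, pooled.size)).copy(),
                        axis=1)
    null = _auc_many(perm, a.size)
    lo, hi = np.percentile(null, [2.5, 97.5])
    tail = min(np.sum(null >= observed), np.sum(null <= observed))
    p = min(1.0, 2.0 * (1 + tail) / (1 + n_perm))
    return observed, float(p), (float(lo), float(hi))


def population_auc(rates_z: np.ndarray, class_masks: dict, comparison: str,
                   n_perm: int = 2000, seed: int = 0,
                   neuron_ids=None) -> list[AUCResult]:
    """AUC + permutation significance for every neuron.

    ``rates_z`` must already be z-scored per neuron over the full
    stimulus set; ``comparison`` is "equi_vs_low" (AUC > 0.5 prefers the
    low-luminance class) or "high_vs_equi" (AUC > 0.5 prefers the
    equiluminant class).
    """
    first, second = {"equi_vs_low": ("equi", "low"),
                     "high_vs_equi": ("high", "equi")}[comparison]
    a_mask, b_mask = class_masks[first], class_masks[second]
    rng = np.random.default_rng(seed)
    out = []
    for i, row in enumerate(np.asarray(rates_z, dtype=float)):
        auc, p, band = auc_permutation_test(
            row[a_mask], row[b_mask], n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        out.append(AUCResult(
            neuron_id=(neuron_ids[i] if neuron_ids is not None else str(i)),
            comparison=comparison, auc=auc, p_perm=p,
            significant=bool(auc < band[0] or auc > band[1]),
        ))
    return out


def circular_align(peak_ref: float, peak_other: float) -> float:
    """Unwrap ``peak_other`` by a multiple of 360 to lie nearest the
    reference peak; e.g. reference 10 with other 355 aligns to -5."""
    return float(unwrap_near(peak_ref, peak_other))


def peak_correlation_bootstrap(peaks_a, peaks_b, n_boot: int = 200,
                               half_fraction: float = 0.5, seed: int = 0):
    """Bootstrap distribution of the cross-luminance peak correlation.

    On each bootstrap, half of the matched neuron list is drawn without
    replacement; peaks from condition b are circularly aligned to their
    condition-a partners before the Pearson correlation. Returns
    (r_values, fisher_z_values) arrays of length n_boot.
    """
    peaks_a = np.asarray(peaks_a, dtype=float)
    peaks_b = np.asarray(peaks_b, dtype=float)
    if peaks_a.shape != peaks_b.shape:
        raise ValueError("matched peak lists must have equal length")
    n = peaks_a.size
    k = max(3, int(round(half_fraction * n)))
    rng = np.random.default_rng(seed)
    aligned = unwrap_near(peaks_a, peaks_b)
    r_vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        r_vals[i] = _safe_pearson(peaks_a[idx], aligned[idx])
    z_vals = np.arctanh(np.clip(r_vals, -1 + 1e-15, 1 - 1e-15))
    capped = np.abs(z_vals) > Z_CAP
    if np.any(capped):
        warnings.warn("Fisher z capped for |r| ~ 1 bootstrap samples")
        z_vals = np.clip(z_vals, -Z_CAP, Z_CAP)
    return r_vals, z_vals


def _safe_pearson(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compare_population_correlations(peaks_a1, peaks_b1, peaks_a2, peaks_b2,
                                    reps: int = 1000, n_boot: int = 200,
                                    seed: int = 0):
    """Bootstrap-then-t comparison of two populations' peak correlations.

    For each of ``reps`` replicates, both populations' Fisher-z bootstrap
    distributions are regenerated and compared by a two-sample t test;
    the reported p is the median over replicates with a percentile 95% CI.
    """
    rng = np.random.default_rng(seed)
    ps = np.empty(reps)
    for i in range(reps):
        _, z1 = peak_correlation_bootstrap(
            peaks_a1, peaks_b1, n_boot=n_boot, seed=int(rng.integers(2**31)))
        _, z2 = peak_correlation_bootstrap(
            peaks_a2, peaks_b2, n_boot=n_boot, seed=int(rng.integers(2**31)))
        ps[i] = stats.ttest_ind(z1, z2).pvalue
    ci = tuple(np.percentile(ps, [2.5, 97.5]))
    return float(np.median(ps)), (float(ci[0]), float(ci[1]))


def peak_shift_bin_test(peaks_brighter, peaks_darker, n_bins: int = 8,
                        n_boot: int = 2000, subsample_fraction: float = 0.9,
                        seed: int = 0, min_cells: int = 3):
    """Per-hue-bin Mann-Whitney test of peak shifts across luminance.

    Cells are binned by their brighter-condition peak into ``n_bins``
    equal arcs (edges 0, 45, ..., 360 by default). Within each bin the
    darker-condition peaks (circularly aligned to the brighter ones) are
    compared with the brighter peaks by a Mann-Whitney U test on
    ``n_boot`` random 90% subsamples; the bin's reported p is the mean
    over subsamples, with a percentile 95% CI.

    Returns a dict {bin_index: (p_mean, (lo, hi), n_cells)}; bins with
    fewer than ``min_cells`` cells are skipped with a warning.
    """
    peaks_brighter = np.asarray(peaks_brighter, dtype=float)
    peaks_darker = np.asarray(peaks_darker, dtype=float)
    aligned_darker = unwrap_near(peaks_brighter, peaks_darker)
    edges = np.linspace(0, 360, n_bins + 1)
    which = np.clip(np.digitize(np.mod(peaks_brighter, 360.0), edges) - 1,
                    0, n_bins - 1)
    rng = np.random.default_rng(seed)
    out = {}
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        if n < min_cells:
            warnings.warn(f"hue bin {b} has {n} cells; skipped")
            continue
        bright = peaks_brighter[sel]
        dark = aligned_darker[sel]
        k = max(2, int(round(subsample_fraction * n)))
        ps = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.choice(n, size=k, replace=False)
            if np.all(bright[idx] == dark[idx]):
                ps[i] = 1.0
            else:
                ps[i] = stats.mannwhitneyu(
                    bright[idx], dark[idx], alternative="two-sided"
                ).pvalue
        lo, hi = np.percentile(ps, [2.5, 97.5])
        out[b] = (float(np.mean(ps)), (float(lo), float(hi)), n)
    return out
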