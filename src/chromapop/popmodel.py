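"""Narrowness x uniformity model-population grid search.

The central question: which combination of per-cell tuning narrowness
(width w) and population-level color-space uniformity (fraction of cells
with uniformly distributed peaks versus peaks biased toward the cardinal
or unique-hue angles) best accounts for a population of recorded
responses?

For each grid cell, many model populations are simulated. Each model
cell's saturation-scaled, normalized tuning function (evaluated at the
45 hues of one luminance class) is compared with one recorded neuron's
raw 45-hue responses after both populations have been rank-ordered by
peak response angle. The match statistic of a grid cell is the median
R^2 over all iterations x rank-matched pairs, displayed as a heat map;
the best-fitting model is the argmax cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._angles import circ_dist
from .synth import _sample_peaks, model_population_rates
from .tuning import peak_angle

DEFAULT_WIDTHS = tuple(range(84, 361, 12))
DEFAULT_FRACTIONS = (0.0, 0.25, 0.5, 0.78, 1.0)


@dataclass
class GridResult:
    widths: tuple
    fractions_uniform: tuple
    median_r2: np.ndarray          # widths x fractions, raw (may be ~0)
    best_cell: tuple               # (width, fraction) attaining the max
    iterations: int
    bias_family: str

    def heatmap(self) -> np.ndarray:
        """Display copy with negative values floored at 0."""
        return np.clip(self.median_r2, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.median_r2,
            index=pd.Index(self.widths, name="width_deg"),
            columns=pd.Index(self.fractions_uniform, name="fraction_uniform"),
        )


def _rank_by_peak(rates: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Row order sorting neurons by their peak angle.

    Peak ties inherit the argmax convention of :func:`tuning.peak_angle`
    (first angle in ascending order); equal peak angles are broken by
    row index for determinism.
    """
    peaks = np.array([peak_angle(r, angles) for r in rates])
    return np.lexsort((np.arange(len(peaks)), peaks))


def _pairwise_r2(a: np.ndarray, b: np.ndarray, definition: str) -> np.ndarray:
    """Row-wise R^2 between two equally shaped matrices.

    "pearson2": squared Pearson correlation (invariant to the min-max
    normalization applied upstream). "regression": 1 - SSres/SStot of b
    predicted by a after both rows are min-max normalized.
    """
    if definition == "pearson2":
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        num = (ac * bc).sum(axis=1)
        den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        return r ** 2
    if definition == "regression":
        def norm(m):
            lo = m.min(axis=1, keepdims=True)
            span = m.max(axis=1, keepdims=True) - lo
            span = np.where(span <= 1e-15, 1.0, span)
            return (m - lo) / span
        an, bn = norm(a), norm(b)
        ss_res = ((bn - an) ** 2).sum(axis=1)
        ss_tot = ((bn - bn.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    raise ValueError(f"unknown R^2 definition {definition!r}")


def match_once(model_rates: np.ndarray, recorded_rates: np.ndarray,
               angles: np.ndarray, r2_definition: str = "pearson2") -> np.ndarray:
    """R^2 per rank-matched (model, recorded) neuron pair.

    Both matrices are neurons x stimuli over the same 45 hues of one
    luminance class; model rows are normalized tuning functions, recorded
    rows are raw responses. Neuron counts must agree.
    """
    model_rates = np.asarray(model_rates, dtype=float)
    recorded_rates = np.asarray(recorded_rates, dtype=float)
    if model_rates.shape[0] != recorded_rates.shape[0]:
        raise ValueError(
            "model and recorded populations must have equal neuron counts "
            f"({model_rates.shape[0]} vs {recorded_rates.shape[0]})"
        )
    angles = np.asarray(angles, dtype=float)
    m = model_rates[_rank_by_peak(model_rates, angles)]
    r = recorded_rates[_rank_by_peak(recorded_rates, angles)]
    return _pairwise_r2(m, r, r2_definition)


def run_grid(recorded_rates: np.ndarray, table_class: pd.DataFrame,
             widths=DEFAULT_WIDTHS, fractions=DEFAULT_FRACTIONS,
             bias_family: str = "cardinal", iterations: int = 1000,
             seed: int = 0, n_model: int | None = None,
             use_saturation: bool = True,
             r2_definition: str = "pearson2") -> GridResult:
    """Median-R^2 heat map over the narrowness x uniformity grid.

    ``recorded_rates`` is neurons x 45 (one luminance class, raw rates).
    When the recorded population exceeds ``n_model`` neurons it is
    subsampled afresh on every iteration, mirroring the equal-count
    comparison between populations of different sizes.
    """
    recorded_rates = np.asarray(recorded_rates, dtype=float)
    angles = table_class["hue_angle_deg"].to_numpy(dtype=float)
    n_rec = recorded_rates.shape[0]
    n_model = n_model or min(n_rec, 181)
    if n_model > n_rec:
        raise ValueError("n_model exceeds recorded population size")
    rng = np.random.default_rng(seed)
    rec_order = _rank_by_peak(recorded_rates, angles)
    rec_sorted = recorded_rates[rec_order]

    median_r2 = np.empty((len(widths), len(fractions)))
    for wi, w in enumerate(widths):
        for fi, frac in enumerate(fractions):
            vals = np.empty((iterations, n_model))
            for it in range(iterations):
                peaks = _sample_peaks(rng, n_model, bias_family, frac)
                model = model_population_rates(
                    peaks, w, table_class, use_saturation=use_saturation
                )
                if n_model < n_rec:
                    keep = np.sort(rng.choice(n_rec, size=n_model, replace=False))
                    rec = rec_sorted[keep]
                else:
                    rec = rec_sorted
                m = model[_rank_by_peak(model, angles)]
                vals[it] = _pairwise_r2(m, rec, r2_definition)
            median_r2[wi, fi] = np.median(vals)
    best = np.unravel_index(np.argmax(median_r2), median_r2.shape)
    return GridResult(
        widths=tuple(widths),
        fractions_uniform=tuple(fractions),
        median_r2=median_r2,
        best_cell=(widths[best[0]], fractions[best[1]]),
        iterations=iterations,
        bias_family=bias_family,
    )


def peak_distribution(pop_rates: np.ndarray, table_class: pd.DataFrame,
                      bins: int = 45) -> pd.Series:
    """Count of neurons peaking at each hue of one luminance class.

    ``bins=45`` counts over the stimulus hues themselves; ``bins=21``
    reassigns each peak to the circularly nearest of the 21 subsampled
    hues.
    """
    angles = table_class["hue_angle_deg"].to_numpy(dtype=float)
    peaks = np.array([peak_angle(r, angles) for r in np.asarray(pop_rates, float)])
    if bins == 45:
        centers = np.sort(angles)
    elif bins == 21:
        centers = np.sort(
            table_class.loc[table_class["in_subsample21"], "hue_angle_deg"]
            .to_numpy(dtype=float)
        )
    else:
        raise ValueError("bins must be 45 or 21")
    nearest = np.argmin(circ_dist(peaks[:, None], centers[None, :]), axis=1)
    counts = np.bincount(nearest, minlength=len(centers))
    return pd.Series(counts, index=pd.Index(centers, name="hue_angle_deg"),
                     name="n_cells")
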