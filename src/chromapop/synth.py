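"""Synthetic neural populations with known ground truth.

Three population kinds emulate the qualitative phenomenology of the
recorded cell classes:

* ``glob`` — narrow hue tuning (widths around 90-105 degrees), peaks that
  barely move across luminance classes, and balanced response gains at
  the three luminance levels;
* ``interglob`` — broad tuning (widths around 120 degrees), larger
  cross-luminance peak jitter, and gains favoring luminance contrast
  (low and high classes) over the equiluminant class;
* ``lgn`` — linear tuning (width exactly 180) with peaks biased toward
  the cone-opponent cardinal angles (28% uniform, 72% cardinal).

Responses are generated from the truncated raised-cosine tuning model,
scaled by each stimulus's CIELUV saturation (the stimulus set confounds
hue and saturation, and model cells inherit that confound), plus a
baseline rate. Trial noise is Poisson on spike counts within the
response window by default; a Gaussian option exists for analytic tests.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._angles import wrap360
from .config import CARDINAL_ANGLES, LUMINANCE_CLASSES, UNIQUE_HUE_ANGLES
from .tuning import ss_curve

_FAMILY_ANGLES = {
    "cardinal": CARDINAL_ANGLES,
    "unique_hue": UNIQUE_HUE_ANGLES,
}

# Emulation defaults for the recorded-like generators. These are the
# package's standing study conditions, not measurements.
KIND_PARAMS = {
    "glob": dict(
        width_mean=95.0, width_sd=20.0, width_clip=(50.0, 200.0),
        peak_jitter_sd=4.0, gains=(1.0, 1.0, 1.0), gain_jitter_sd=0.3,
        fmin_range=(1.0, 5.0), fmax_range=(20.0, 45.0),
        fraction_uniform=1.0, bias_family="cardinal",
    ),
    # interglob cells are broad and weakly modulated (low drive relative
    # to baseline), which yields the poorer tuning fits and the less
    # hue-organized representational geometry of that population
    "interglob": dict(
        width_mean=125.0, width_sd=30.0, width_clip=(60.0, 300.0),
        peak_jitter_sd=25.0, gains=(1.25, 0.7, 1.25), gain_jitter_sd=0.3,
        fmin_range=(4.0, 10.0), fmax_range=(8.0, 20.0),
        fraction_uniform=1.0, bias_family="cardinal",
    ),
    "lgn": dict(
        width_mean=180.0, width_sd=0.0, width_clip=(180.0, 180.0),
        peak_jitter_sd=0.0, gains=(1.0, 1.0, 1.0), gain_jitter_sd=0.0,
        fmin_range=(1.0, 5.0), fmax_range=(20.0, 45.0),
        fraction_uniform=0.28, bias_family="cardinal",
    ),
}

STIM_DURATION_S = 0.2  # presentation time used to convert rates to counts


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one synthetic neuron."""

    neuron_id: str
    peak_angle_deg: float
    width_deg: float
    fmin_hz: float = 2.0
    fmax_hz: float = 30.0
    luminance_gain: tuple = (1.0, 1.0, 1.0)     # (low, equi, high)
    peak_jitter_by_class: tuple = (0.0, 0.0, 0.0)
    noise_model: str = "poisson"                # or "gaussian"
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.width_deg <= 0:
            raise ValueError("width_deg must be positive")
        if self.fmax_hz < 0 or any(g < 0 for g in self.luminance_gain):
            raise ValueError("rates and gains must be nonnegative")


@dataclass
class PopulationSpec:
    """Peak-angle sampling law for a model population."""

    n_neurons: int
    bias_family: str = "cardinal"   # cardinal | unique_hue | uniform
    fraction_uniform: float = 1.0
    width_deg: float = 180.0
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0.0 <= self.fraction_uniform <= 1.0:
            raise ValueError("fraction_uniform must be in [0, 1]")


@dataclass
class ResponseMatrix:
    """Mean rates (neurons x stimuli), optional trials, and metadata."""

    rates: np.ndarray
    stimulus_ids: list
    neurons: list = field(default_factory=list)   # NeuronSpec ground truth
    trials: np.ndarray | None = None              # neurons x stimuli x trials
    baseline_hz: np.ndarray | None = None

    @property
    def n_neurons(self):
        return self.rates.shape[0]

    def subset(self, stim_mask):
        """Restrict to a boolean/index stimulus subset (columns)."""
        ids = list(np.asarray(self.stimulus_ids)[stim_mask])
        return ResponseMatrix(
            rates=self.rates[:, stim_mask],
            stimulus_ids=ids,
            neurons=self.neurons,
            trials=None if self.trials is None else self.trials[:, stim_mask],
            baseline_hz=self.baseline_hz,
        )


def sample_peak_angles(spec: PopulationSpec) -> np.ndarray:
    """Draw peak angles: uniform over integer degrees with probability
    ``fraction_uniform``, otherwise within +/-5 degrees of one of the four
    family angles (cardinal or unique-hue), chosen equiprobably."""
    rng = np.random.default_rng(spec.seed)
    return _sample_peaks(rng, spec.n_neurons, spec.bias_family, spec.fraction_uniform)


def _sample_peaks(rng, n, bias_family, fraction_uniform):
    if bias_family == "uniform":
        fraction_uniform = 1.0
        family = None
    else:
        family = np.asarray(_FAMILY_ANGLES[bias_family], dtype=float)
    uniform_mask = rng.random(n) < fraction_uniform
    out = np.empty(n)
    out[uniform_mask] = rng.integers(1, 361, size=int(uniform_mask.sum())).astype(float)
    n_fam = int((~uniform_mask).sum())
    if n_fam:
        centers = family[rng.integers(0, len(family), size=n_fam)]
        out[~uniform_mask] = wrap360(centers + rng.uniform(-5, 5, size=n_fam))
    return out


def model_cell_response(neuron: NeuronSpec, table: pd.DataFrame,
                        use_saturation: bool = True) -> np.ndarray:
    """Normalized model response of one cell to one luminance class.

    Evaluates the tuning curve at each stimulus hue, optionally multiplies
    by the stimulus saturation, then min-max normalizes to [0, 1].
    """
    if table["luminance_class"].nunique() != 1:
        raise ValueError("stimuli must share one luminance class")
    theta = table["hue_angle_deg"].to_numpy(dtype=float)
    r = ss_curve(theta, 0.0, 1.0, neuron.width_deg, neuron.peak_angle_deg)
    if use_saturation:
        r = r * table["sat_luv"].to_numpy(dtype=float)
    span = r.max() - r.min()
    if span <= 1e-15:
        raise ValueError(f"degenerate (flat) model cell {neuron.neuron_id}")
    return (r - r.min()) / span


def model_population_rates(peaks, width_deg, table: pd.DataFrame,
                           use_saturation: bool = True) -> np.ndarray:
    """Vectorized normalized responses for many model cells (one class).

    Cells whose saturation-scaled curve is flat (possible for very broad
    tuning) are normalized to zero rather than raised as errors; the
    grid search treats them as uninformative.
    """
    theta = table["hue_angle_deg"].to_numpy(dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    d = np.abs((theta[None, :] - peaks[:, None] + 180.0) % 360.0 - 180.0)
    r = np.where(d < width_deg,
                 np.cos(np.pi * d / (2.0 * width_deg)) ** 2, 0.0)
    if use_saturation:
        r = r * table["sat_luv"].to_numpy(dtype=float)[None, :]
    lo = r.min(axis=1, keepdims=True)
    span = r.max(axis=1, keepdims=True) - lo
    span = np.where(span <= 1e-15, 1.0, span)
    return (r - lo) / span


def simulate_recorded_population(kind: str, n: int, table: pd.DataFrame,
                                 seed: int = 0, n_trials: int = 5,
                                 noise: str = "poisson",
                                 noise_sd: float = 0.0) -> ResponseMatrix:
    """Trial-level noisy responses of a recorded-like population to all
    135 stimuli. ``noise`` may be "poisson", "gaussian", or "none"."""
    if kind not in KIND_PARAMS:
        raise ValueError(f"unknown population kind {kind!r}")
    p = KIND_PARAMS[kind]
    rng = np.random.default_rng(seed)
    peaks = _sample_peaks(rng, n, p["bias_family"], p["fraction_uniform"])
    widths = np.clip(
        rng.normal(p["width_mean"], p["width_sd"], size=n), *p["width_clip"]
    )
    fmin = rng.uniform(*p["fmin_range"], size=n)
    fmax = rng.uniform(*p["fmax_range"], size=n)
    jitter = rng.normal(0.0, p["peak_jitter_sd"], size=(n, 3))
    # per-neuron gain heterogeneity: individual cells may prefer any
    # luminance class even when the population-level gains are balanced
    gains = np.clip(
        np.asarray(p["gains"])[None, :]
        * (1.0 + rng.normal(0.0, p["gain_jitter_sd"], size=(n, 3))),
        0.05, None,
    )
    neurons = [
        NeuronSpec(
            neuron_id=f"n{i:04d}",
            peak_angle_deg=float(peaks[i]),
            width_deg=float(widths[i]),
            fmin_hz=float(fmin[i]),
            fmax_hz=float(fmax[i]),
            luminance_gain=tuple(gains[i]),
            peak_jitter_by_class=tuple(jitter[i]),
            noise_model=noise,
            noise_sd=noise_sd,
        )
        for i in range(n)
    ]
    n_stim = len(table)
    mean_rates = np.zeros((n, n_stim))
    sat = table["sat_luv"].to_numpy(dtype=float)
    theta = table["hue_angle_deg"].to_numpy(dtype=float)
    for ci, cls in enumerate(LUMINANCE_CLASSES):
        mask = (table["luminance_class"] == cls).to_numpy()
        for i, nrn in enumerate(neurons):
            alpha = wrap360(nrn.peak_angle_deg + nrn.peak_jitter_by_class[ci])
            shape = ss_curve(theta[mask], 0.0, 1.0, nrn.width_deg, alpha)
            drive = shape * sat[mask] * nrn.luminance_gain[ci]
            mean_rates[i, mask] = nrn.fmin_hz + nrn.fmax_hz * drive
    if noise == "none":
        trials = np.repeat(mean_rates[:, :, None], n_trials, axis=2)
    elif noise == "poisson":
        counts = rng.poisson(mean_rates[:, :, None] * STIM_DURATION_S,
                             size=(n, n_stim, n_trials))
        trials = counts / STIM_DURATION_S
    elif noise == "gaussian":
        trials = mean_rates[:, :, None] + rng.normal(
            0.0, noise_sd, size=(n, n_stim, n_trials)
        )
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ResponseMatrix(
        rates=trials.mean(axis=2),
        stimulus_ids=list(table["stimulus_id"]),
        neurons=neurons,
        trials=trials,
        baseline_hz=fmin,
    )


def presentation_schedule(table: pd.DataFrame, include_black_white: bool = True,
                          seed: int = 0) -> list:
    """Pseudorandom order of one presentation cycle.

    All 135 colors once each; when ``include_black_white`` is set, three
    'white' and three 'black' presentations are interleaved, for a cycle
    length of 141.
    """
    items = list(table["stimulus_id"])
    if include_black_white:
        items += ["white"] * 3 + ["black"] * 3
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def responses_to_long_df(pop: ResponseMatrix) -> pd.DataFrame:
    """Long-format trial table: neuron_id, stimulus_id, trial, rate_hz."""
    if pop.trials is None:
        raise ValueError("population has no trial-level data")
    n, s, t = pop.trials.shape
    idx = pd.MultiIndex.from_product(
        [[nr.neuron_id for nr in pop.neurons] or range(n),
         pop.stimulus_ids, range(t)],
        names=["neuron_id", "stimulus_id", "trial"],
    )
    return pd.DataFrame(
        {"rate_hz": pop.trials.reshape(-1)}, index=idx
    ).reset_index()
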