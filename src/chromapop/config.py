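"""Configuration constants and run configuration.

Houses the color-space constants used throughout the package:

* the monitor-gamut triangle in CIE 1976 (u', v') chromaticity coordinates,
* the adapting gray (neutral) point,
* the three stimulus luminance levels (cd/m^2),
* the cardinal hue angles (LGN cone-opponent axes) and the unique-hue
  angles, both expressed as CIELUV hue angles about the gray point,
* a coarse spectrum-locus polyline used by the CIELUV saturation ratio,
* a configurable linear map from (u', v') offsets to a cone-opponent
  (MB-DKL-like) plane, used by the DKL saturation metric,
* warm/cool hue arcs for the warm-bias permutation test.

All of these can be overridden from a YAML file; the defaults are the
conditions the rest of the package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

# Hue angles (CIELUV degrees) of the cone-opponent cardinal axes
# (L-M poles and S poles) used to model retina/LGN color bias.
CARDINAL_ANGLES = (353.0, 100.0, 173.0, 280.0)

# Hue angles of the psychologically privileged unique hues
# (red, yellow-green region etc.), used for the unique-hue-biased model.
UNIQUE_HUE_ANGLES = (14.0, 70.0, 139.0, 238.0)

# Stimulus luminance levels, cd/m^2: below, at, and above the adapting
# background (which is at the equiluminant level).
LUMINANCE_LEVELS = {"low": 0.62, "equi": 3.05, "high": 7.8}
LUMINANCE_CLASSES = ("low", "equi", "high")

# CRT-like monitor primaries in (u', v'). Approximate Rec.601-era phosphors.
DEFAULT_PRIMARIES = {
    "red": (0.4330, 0.5284),
    "green": (0.1089, 0.5618),
    "blue": (0.1754, 0.1579),
}

# Adapting neutral point (approximately D65 in u'v').
DEFAULT_GRAY = (0.1978, 0.4683)

# Coarse polyline approximating the spectrum locus (plus the purple line)
# in (u', v'). Only the shape matters: it bounds the gamut triangle and
# supplies the denominator of the CIELUV saturation ratio.
DEFAULT_SPECTRUM_LOCUS = (
    (0.2522, 0.0105),   # ~400 nm
    (0.1813, 0.0263),   # ~450 nm
    (0.1441, 0.0828),   # ~460 nm
    (0.0913, 0.1327),   # ~480 nm
    (0.0461, 0.2255),   # ~490 nm
    (0.0036, 0.3135),   # ~500 nm
    (0.0139, 0.4462),   # ~510 nm
    (0.0595, 0.5464),   # ~520 nm
    (0.0929, 0.5669),   # ~535 nm
    (0.1127, 0.5785),   # ~550 nm
    (0.1712, 0.5868),   # ~570 nm
    (0.2578, 0.5781),   # ~590 nm
    (0.3833, 0.5572),   # ~620 nm
    (0.5298, 0.5293),   # ~660 nm
    (0.6234, 0.5065),   # ~700 nm; purple line closes back to ~400 nm
)

# Default linear map from (u' - gray_u, v' - gray_v) to a cone-opponent
# plane. Monitor spectra are required for an exact CIE->MB-DKL conversion,
# so this matrix is a config input; the default stretches the L-M-like
# axis relative to the S-like axis, a qualitative feature of DKL space.
DEFAULT_UV_TO_DKL = ((2.0, 0.35), (-0.3, 1.0))

# Warm/cool hue arcs (start, end), degrees counterclockwise from start to
# end. Endpoints approximate the Munsell RP-to-Y span (pink/red/orange/
# yellow) and G-to-PM span (green/cyan/blue/violet) as CIELUV hue angles.
DEFAULT_WARM_ARC = (320.0, 90.0)
DEFAULT_COOL_ARC = (100.0, 300.0)


@dataclass
class StimulusConfig:
    """Geometry of the stimulus set."""

    n_hues: int = 45
    n_subsample: int = 21
    n_triplets: int = 17
    gray: tuple = DEFAULT_GRAY
    primaries: dict = field(default_factory=lambda: dict(DEFAULT_PRIMARIES))
    spectrum_locus: tuple = DEFAULT_SPECTRUM_LOCUS
    uv_to_dkl: tuple = DEFAULT_UV_TO_DKL
    triplet_tolerance_deg: float = 3.0


@dataclass
class RunConfig:
    """Master configuration for an end-to-end pipeline run."""

    seed: int = 0
    population_kind: str = "glob"
    n_neurons: int = 120
    n_trials: int = 5
    grid_widths: tuple = (84, 132, 180, 240, 360)
    grid_fractions: tuple = (0.0, 0.25, 0.5, 0.78, 1.0)
    grid_iterations: int = 50
    bias_family: str = "cardinal"
    n_perm: int = 500
    n_boot: int = 200
    mds_dim: int = 2
    mds_restarts: int = 5
    run_decoding: bool = True
    out_dir: str = "chromapop_out"
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stim = StimulusConfig(**raw.pop("stimulus", {}))
        cfg = cls(**raw, stimulus=stim) if "stimulus" not in raw else cls(**raw)
        cfg.stimulus = stim
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def uv_to_dkl_matrix(cfg: StimulusConfig) -> np.ndarray:
    return np.asarray(cfg.uv_to_dkl, dtype=float)
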