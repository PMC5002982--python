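"""Stimulus geometry in CIELUV chromaticity space.

The stimulus set consists of three luminance classes (low, equi, high),
each holding 45 maximally saturated colors on the monitor-gamut triangle
in (u', v'). Hue is the four-quadrant angle about the adapting gray
point. Two saturation metrics are attached to every stimulus:

* ``sat_luv`` — the ratio of the gray-to-stimulus distance over the
  gray-to-spectrum-locus distance along the same ray (a perceptual,
  bounded-in-[0,1] measure);
* ``sat_dkl`` — the Euclidean distance from gray in a cone-opponent
  plane obtained by a configurable linear map of (u', v') offsets
  (a physiological measure, unbounded).

The module also selects the 21 most evenly spaced hues per class and
identifies hue-matched triplets (one stimulus per class, pairwise hue
difference within a tolerance), both of which downstream analyses use.

The canonical container is a pandas DataFrame ("stimulus table") with
columns: stimulus_id, luminance_class, luminance_cd_m2, u_prime,
v_prime, hue_angle_deg, sat_luv, sat_dkl, in_subsample21, triplet_id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._angles import wrap360, circ_dist
from .config import (
    LUMINANCE_CLASSES,
    LUMINANCE_LEVELS,
    StimulusConfig,
    uv_to_dkl_matrix,
)

STIMULUS_COLUMNS = [
    "stimulus_id",
    "luminance_class",
    "luminance_cd_m2",
    "u_prime",
    "v_prime",
    "hue_angle_deg",
    "sat_luv",
    "sat_dkl",
    "in_subsample21",
    "triplet_id",
]


class DegenerateHueError(ValueError):
    """Hue angle is undefined at the gray point itself."""


def hue_angle(u, v, gray_u, gray_v):
    """Four-quadrant hue angle (degrees in [0, 360)) about the gray point."""
    du = np.asarray(u, dtype=float) - gray_u
    dv = np.asarray(v, dtype=float) - gray_v
    if np.any((du == 0) & (dv == 0)):
        raise DegenerateHueError("hue angle undefined at the gray point")
    return wrap360(np.degrees(np.arctan2(dv, du)))


def _ray_polygon_t(origin, direction, polygon):
    """Smallest t > 0 where origin + t*direction crosses the closed polygon.

    Returns np.inf when the ray escapes without crossing (degenerate
    polygon or origin outside).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    p1 = poly
    p2 = np.roll(poly, -1, axis=0)
    edge = p2 - p1
    # Solve origin + t d = p1 + s e  via 2x2 cross products.
    denom = direction[0] * (-edge[:, 1]) - direction[1] * (-edge[:, 0])
    rel = p1 - origin
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * (-edge[:, 1]) - rel[:, 1] * (-edge[:, 0])) / denom
        s = (direction[0] * rel[:, 1] - direction[1] * rel[:, 0]) / denom
    ok = (np.abs(denom) > 1e-300) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    return float(np.min(t[ok])) if np.any(ok) else np.inf


def luv_saturation(stimulus_uv, gray_uv, locus):
    """Saturation as |stimulus - gray| / |locus crossing - gray|.

    The denominator is the distance from gray to the spectrum locus along
    the ray through the stimulus, so a stimulus on the locus has
    saturation 1 and the gray point itself has saturation 0.
    """
    stim = np.asarray(stimulus_uv, dtype=float)
    gray = np.asarray(gray_uv, dtype=float)
    d = stim - gray
    r = float(np.hypot(*d))
    if r == 0.0:
        return 0.0
    t = _ray_polygon_t(gray, d, locus)
    if not np.isfinite(t):
        raise ValueError("gray point not strictly inside the locus polygon")
    if t < 1.0 - 1e-9:
        raise ValueError("stimulus lies outside the spectrum locus")
    return min(1.0 / t, 1.0)


def dkl_saturation(stimulus_dkl, gray_dkl):
    """Euclidean distance from the adapting point in cone-opponent space."""
    d = np.asarray(stimulus_dkl, dtype=float) - np.asarray(gray_dkl, dtype=float)
    return float(np.hypot(*d))


def select_even_hues(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Flag, per luminance class, the k stimuli closest to k evenly spaced
    target angles.

    Assignment is globally greedy: among all (target, stimulus) pairs the
    smallest circular deviation is committed first and neither member is
    reused. Returns a copy of the table with ``in_subsample21`` set.
    """
    out = table.copy()
    out["in_subsample21"] = False
    targets = np.arange(k) * 360.0 / k
    for cls, sub in table.groupby("luminance_class", sort=False):
        angles = sub["hue_angle_deg"].to_numpy(dtype=float)
        if len(angles) < k:
            raise ValueError(
                f"class {cls!r} has {len(angles)} stimuli, fewer than k={k}"
            )
        dist = circ_dist(targets[:, None], angles[None, :])
        dist = np.array(dist, dtype=float)
        chosen = []
        for _ in range(k):
            tj, si = np.unravel_index(np.argmin(dist), dist.shape)
            chosen.append(si)
            dist[tj, :] = np.inf
            dist[:, si] = np.inf
        out.loc[sub.index[chosen], "in_subsample21"] = True
    return out


def match_hue_triplets(table: pd.DataFrame, tolerance: float = 3.0) -> pd.DataFrame:
    """Assign hue-matched triplets: one stimulus per luminance class with
    all pairwise circular hue differences within ``tolerance`` degrees.

    Greedy by ascending low-class hue; each stimulus joins at most one
    triplet. Returns a copy with ``triplet_id`` set (pd.NA elsewhere).
    """
    out = table.copy()
    out["triplet_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    classes = list(LUMINANCE_CLASSES)
    present = set(table["luminance_class"])
    if not all(c in present for c in classes):
        raise ValueError("all three luminance classes required")
    subs = {c: table[table["luminance_class"] == c] for c in classes}
    used = {c: set() for c in classes}
    tid = 0
    anchor = subs[classes[0]].sort_values("hue_angle_deg")
    for idx0, row0 in anchor.iterrows():
        a0 = row0["hue_angle_deg"]
        best = None
        for idx1, row1 in subs[classes[1]].iterrows():
            if idx1 in used[classes[1]]:
                continue
            a1 = row1["hue_angle_deg"]
            if circ_dist(a0, a1) > tolerance:
                continue
            for idx2, row2 in subs[classes[2]].iterrows():
                if idx2 in used[classes[2]]:
                    continue
                a2 = row2["hue_angle_deg"]
                if circ_dist(a0, a2) > tolerance or circ_dist(a1, a2) > tolerance:
                    continue
                spread = max(circ_dist(a0, a1), circ_dist(a0, a2), circ_dist(a1, a2))
                if best is None or spread < best[0]:
                    best = (spread, idx1, idx2)
        if best is not None:
            _, idx1, idx2 = best
            out.loc[[idx0, idx1, idx2], "triplet_id"] = tid
            used[classes[1]].add(idx1)
            used[classes[2]].add(idx2)
            tid += 1
    return out


def _gamut_polygon(cfg: StimulusConfig) -> np.ndarray:
    return np.array(
        [cfg.primaries["red"], cfg.primaries["green"], cfg.primaries["blue"]],
        dtype=float,
    )


def _boundary_point_at_angle(angle_deg: float, cfg: StimulusConfig) -> np.ndarray:
    """Point on the gamut-triangle boundary along the ray at ``angle_deg``."""
    gray = np.asarray(cfg.gray, dtype=float)
    d = np.array([np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))])
    t = _ray_polygon_t(gray, d, _gamut_polygon(cfg))
    if not np.isfinite(t):
        raise ValueError("gray point not inside the gamut triangle")
    return gray + t * d


def _primary_angles(cfg: StimulusConfig) -> np.ndarray:
    poly = _gamut_polygon(cfg)
    return hue_angle(poly[:, 0], poly[:, 1], *cfg.gray)


def _base_hue_angles(cfg: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    """n_hues base hue angles with mildly irregular spacing.

    Angular gaps shrink toward the gamut-triangle primaries (the monitor
    set oversamples the high-saturation corners) but keep a floor above
    2 x (filler offset + triplet tolerance), which is what guarantees
    that cross-class hue matching below happens only at designated
    anchor hues.
    """
    n = cfg.n_hues
    prim = _primary_angles(cfg)
    provisional = np.arange(n) * 360.0 / n
    dist = np.min(circ_dist(provisional[:, None], prim[None, :]), axis=1)
    weight = 0.5 + dist / 60.0  # larger gap far from primaries
    weight = weight * rng.uniform(0.9, 1.1, size=n)
    floor = 2.0 * (cfg.triplet_tolerance_deg + 0.6)  # 7.2 at the 3-deg default
    slack = 360.0 - floor * n
    if slack <= 0:
        raise ValueError("n_hues too large for the triplet-isolation floor")
    gaps = floor + slack * weight / weight.sum()
    start = rng.uniform(0, 360)
    return wrap360(start + np.concatenate([[0.0], np.cumsum(gaps[:-1])]))


def generate_stimulus_table(
    cfg: StimulusConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Build the default 135-stimulus table (45 hues x 3 luminance classes).

    The equiluminant class sits at 45 base hue angles on the gamut
    boundary. The low/high classes reuse the base hues with deterministic
    angular offsets: ``n_triplets`` designated anchor hues stay within a
    third of the triplet tolerance of their base angle in every class,
    while all other (filler) hues are displaced by slightly more than the
    tolerance, with opposite signs in the low and high classes. Because
    neighboring base hues are separated by more than twice the filler
    displacement plus tolerance, the hue-matched triplets are exactly
    the anchors, by construction.
    """
    cfg = cfg or StimulusConfig()
    rng = np.random.default_rng(seed)
    base = _base_hue_angles(cfg, rng)
    order = np.argsort(base)
    base = base[order]
    n = cfg.n_hues
    anchor_idx = np.round(np.linspace(0, n - 1, cfg.n_triplets)).astype(int)
    anchor = np.zeros(n, dtype=bool)
    anchor[anchor_idx] = True
    tol = cfg.triplet_tolerance_deg
    filler_sign = rng.choice([-1.0, 1.0], size=n)

    offsets = {"equi": np.zeros(n)}
    for cls, sign in (("low", 1.0), ("high", -1.0)):
        anchor_jitter = rng.uniform(-0.3 * tol, 0.3 * tol, size=n)
        filler_shift = sign * filler_sign * rng.uniform(tol + 0.5, tol + 1.0, size=n)
        offsets[cls] = np.where(anchor, anchor_jitter, filler_shift)

    rows = []
    sid = 0
    for cls in LUMINANCE_CLASSES:
        for i in range(n):
            ang = wrap360(base[i] + offsets[cls][i])
            uv = _boundary_point_at_angle(ang, cfg)
            rows.append(
                {
                    "stimulus_id": f"s{sid:03d}",
                    "luminance_class": cls,
                    "luminance_cd_m2": LUMINANCE_LEVELS[cls],
                    "u_prime": uv[0],
                    "v_prime": uv[1],
                    "hue_angle_deg": float(ang),
                }
            )
            sid += 1
    table = pd.DataFrame(rows)
    mat = uv_to_dkl_matrix(cfg)
    gray = np.asarray(cfg.gray)
    duv = table[["u_prime", "v_prime"]].to_numpy() - gray
    dkl = duv @ mat.T
    table["sat_luv"] = [
        luv_saturation((r.u_prime, r.v_prime), cfg.gray, cfg.spectrum_locus)
        for r in table.itertuples()
    ]
    table["sat_dkl"] = np.hypot(dkl[:, 0], dkl[:, 1])
    table = select_even_hues(table, cfg.n_subsample)
    table = match_hue_triplets(table, tolerance=tol)
    return table.reset_index(drop=True)


def class_table(table: pd.DataFrame, luminance_class: str) -> pd.DataFrame:
    """Rows of one luminance class, sorted by hue angle."""
    sub = table[table["luminance_class"] == luminance_class]
    return sub.sort_values("hue_angle_deg").reset_index(drop=True)
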