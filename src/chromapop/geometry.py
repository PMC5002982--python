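"""Representational geometry: RDMs, Sammon-stress MDS, and RSA.

Each stimulus is represented by the vector of (z-scored) responses it
evokes across the population. The neural representational dissimilarity
matrix (RDM) holds d(si, sj) = 1 - Pearson correlation between those
vectors; the reference RDM holds the circular CIELUV hue-angle distance
between stimuli. Multidimensional scaling minimizes Sammon's stress

    E = (1 / sum_ij d_ij) * sum_ij (d_ij - delta_ij)^2 / d_ij

(sums over i < j, delta = embedded Euclidean distance), which weights
each mismatch inversely by the original dissimilarity, emphasizing the
faithful embedding of nearby stimuli. Representational similarity
analysis correlates the lower triangles of a neural and a reference RDM
and tests the correlation through its Fisher z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from ._angles import circ_dist


@dataclass
class RDM:
    labels: list
    d: np.ndarray
    metric: str                     # "one_minus_pearson" | "circular_angle"

    def tri(self) -> np.ndarray:
        """Lower-triangle entries (condensed form)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]


@dataclass
class Embedding:
    coords: np.ndarray
    stress: float
    k: int
    n_restarts: int


def zscore_rates(rates: np.ndarray) -> np.ndarray:
    """Z-score each neuron (row) across the stimuli provided."""
    rates = np.asarray(rates, dtype=float)
    mu = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, keepdims=True)
    sd = np.where(sd <= 1e-15, 1.0, sd)
    return (rates - mu) / sd


def neural_rdm(pop_rates: np.ndarray, labels=None,
               normalize: bool = True) -> RDM:
    """Correlation-distance RDM between stimulus response vectors.

    ``pop_rates`` is neurons x stimuli. Stimuli whose response vector has
    zero variance across neurons (undefined correlation) are dropped
    listwise, mirroring the treatment of degenerate model-cell responses.
    """
    rates = np.asarray(pop_rates, dtype=float)
    if rates.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    if normalize:
        rates = zscore_rates(rates)
    if labels is None:
        labels = list(range(rates.shape[1]))
    sd = rates.std(axis=0)
    keep = sd > 1e-12
    rates = rates[:, keep]
    labels = [l for l, k in zip(labels, keep) if k]
    corr = np.corrcoef(rates.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return RDM(labels=labels, d=d, metric="one_minus_pearson")


def hue_angle_rdm(table_class: pd.DataFrame) -> RDM:
    """Circular hue-angle distance RDM for one luminance class."""
    if table_class["luminance_class"].nunique() != 1:
        raise ValueError("one luminance class at a time")
    ang = table_class["hue_angle_deg"].to_numpy(dtype=float)
    d = np.asarray(circ_dist(ang[:, None], ang[None, :]), dtype=float)
    return RDM(labels=list(table_class["stimulus_id"]), d=d,
               metric="circular_angle")


def _sammon_stress_grad(x_flat, d, k, scale):
    x = x_flat.reshape(-1, k)
    delta = squareform(pdist(x))
    iu = np.triu_indices(len(x), k=1)
    diff = delta[iu] - d[iu]
    stress = np.sum(diff ** 2 / d[iu]) / scale
    # gradient; diagonal d entries are 0 but zeroed out of coef below
    d_safe = d + np.eye(len(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(delta > 1e-12, 1.0 / delta, 0.0)
    coef = 2.0 / scale * (delta - d) / d_safe * w
    np.fill_diagonal(coef, 0.0)
    grad = (coef[:, :, None] * (x[:, None, :] - x[None, :, :])).sum(axis=1)
    return stress, grad.ravel()


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)[None, :]


def sammon_mds(rdm: RDM, k: int = 2, n_restarts: int = 5,
               seed: int = 0) -> Embedding:
    """Minimize Sammon stress over k-dimensional coordinates.

    Starts from the classical (Torgerson) MDS solution plus
    ``n_restarts - 1`` seeded random configurations and keeps the best.
    Zero off-diagonal dissimilarities are floored at a small epsilon so
    the Sammon weights stay finite.
    """
    d = np.asarray(rdm.d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("RDM contains non-finite entries")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    d = d.copy()
    eps = max(1e-6, 1e-4 * np.mean(d[iu])) if np.any(d[iu] <= 0) else 0.0
    if eps:
        off = d[iu]
        d[iu] = np.maximum(off, eps)
        d.T[iu] = d[iu]
    scale = float(np.sum(d[iu]))
    rng = np.random.default_rng(seed)
    spread = np.mean(d[iu])
    starts = [_classical_mds(d, k)]
    starts += [rng.normal(0.0, spread, size=(n, k)) for _ in range(n_restarts - 1)]
    best = None
    for x0 in starts:
        res = minimize(
            _sammon_stress_grad, x0.ravel(), args=(d, k, scale), jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return Embedding(coords=best.x.reshape(n, k), stress=float(best.fun),
                     k=k, n_restarts=n_restarts)


def rsa_correlation(neural: RDM, reference: RDM):
    """Pearson r between two RDMs' lower triangles, with a Fisher-z test.

    Stimuli missing from either RDM (dropped degenerate entries) are
    excluded pairwise by label before the correlation. The p-value is a
    two-tailed test of z = atanh(r) with standard error 1/sqrt(m - 3)
    over the m retained pairs.
    """
    common = [l for l in neural.labels if l in set(reference.labels)]
    if len(common) < 3:
        raise ValueError("fewer than 3 common stimuli")
    ni = [neural.labels.index(l) for l in common]
    ri = [reference.labels.index(l) for l in common]
    dn = neural.d[np.ix_(ni, ni)]
    dr = reference.d[np.ix_(ri, ri)]
    iu = np.triu_indices(len(common), k=1)
    x, y = dn[iu], dr[iu]
    if len(x) < 3:
        raise ValueError("fewer than 3 valid RDM pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    m = len(x)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    p = 2.0 * stats.norm.sf(abs(z) * np.sqrt(max(m - 3, 1)))
    return r, float(p)


def rsa_bootstrap(pop_rates: np.ndarray, reference: RDM, labels,
                  n_boot: int = 200, seed: int = 0) -> np.ndarray:
    """Bootstrap (over neurons, with replacement) distribution of the
    RSA correlation between a population's RDM and a reference RDM."""
    rates = np.asarray(pop_rates, dtype=float)
    rng = np.random.default_rng(seed)
    n = rates.shape[0]
    out = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rdm = neural_rdm(rates[idx], labels=labels)
        out[i], _ = rsa_correlation(rdm, reference)
    return out


def compare_rsa_paired(r_boot_a, r_boot_b) -> float:
    """Paired two-tailed t test on Fisher-z transformed correlations."""
    za = np.arctanh(np.clip(np.asarray(r_boot_a, float), -1 + 1e-15, 1 - 1e-15))
    zb = np.arctanh(np.clip(np.asarray(r_boot_b, float), -1 + 1e-15, 1 - 1e-15))
    if za.shape != zb.shape:
        raise ValueError("paired distributions must have equal length")
    if np.allclose(za, zb):
        return 1.0
    return float(stats.ttest_rel(za, zb).pvalue)
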