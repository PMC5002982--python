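"""End-to-end orchestration: synth -> fits -> analyses -> report bundle.

One master seed fans out deterministically to every stochastic stage, so
rerunning the same configuration reproduces every output byte for byte.
Each stage writes its own CSV/JSON artifact plus entries in a combined
machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, geometry, luminance, popmodel, selectivity, stimuli
from .config import LUMINANCE_CLASSES, RunConfig
from .synth import simulate_recorded_population
from .tuning import fit_population, peak_angle as tuning_peak_angle

log = logging.getLogger("chromapop")


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def validate_io(responses: pd.DataFrame, table: pd.DataFrame):
    """Schema and alignment checks for a responses/stimuli pair."""
    need_resp = {"neuron_id", "stimulus_id", "rate_hz"}
    need_stim = {"stimulus_id", "luminance_class", "u_prime", "v_prime",
                 "hue_angle_deg", "sat_luv"}
    missing = need_resp - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")
    missing = need_stim - set(table.columns)
    if missing:
        raise ValueError(f"stimulus table missing columns: {sorted(missing)}")
    for col in need_resp:
        if responses[col].isna().any():
            raise ValueError(f"NaNs in required responses column {col!r}")
    unknown = set(responses["stimulus_id"]) - set(table["stimulus_id"])
    if unknown:
        raise ValueError(
            f"response stimuli absent from stimulus table: {sorted(unknown)[:5]}"
        )
    return responses, table


def _class_block(pop, table, cls):
    """(rates, class subtable) for one luminance class, hue-sorted."""
    sub = stimuli.class_table(table, cls)
    idx = [pop.stimulus_ids.index(s) for s in sub["stimulus_id"]]
    return pop.rates[:, idx], sub


def run_all(cfg: RunConfig) -> dict:
    """Run every stage on one synthetic population; returns the summary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    summary: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "population_kind": cfg.population_kind,
    }

    def stage(name):
        log.info("stage: %s", name)

    stage("stimuli")
    table = stimuli.generate_stimulus_table(cfg.stimulus,
                                            seed=_stage_seed(cfg.seed, "stimuli"))
    table.to_csv(out_dir / "stimuli.csv", index=False)

    stage("synth")
    pop = simulate_recorded_population(
        cfg.population_kind, cfg.n_neurons, table,
        seed=_stage_seed(cfg.seed, "synth"), n_trials=cfg.n_trials,
    )
    rates_df = pd.DataFrame(pop.rates, columns=pop.stimulus_ids)
    rates_df.insert(0, "neuron_id", [n.neuron_id for n in pop.neurons])
    rates_df.to_csv(out_dir / "responses_mean.csv", index=False)

    stage("fit")
    fits = {}
    fit_rows = []
    for cls in LUMINANCE_CLASSES:
        rates, sub = _class_block(pop, table, cls)
        sel = sub["in_subsample21"].to_numpy()
        cls_fits = fit_population(
            rates[:, sel], sub.loc[sel, "hue_angle_deg"].to_numpy(),
            luminance_class=cls,
        )
        fits[cls] = cls_fits
        for nrn, f in zip(pop.neurons, cls_fits):
            fit_rows.append({
                "neuron_id": nrn.neuron_id, "luminance_class": cls,
                "fmin": f.fmin, "fmax": f.fmax, "width_deg": f.width_w,
                "alpha_deg": f.peak_alpha, "r2": f.r2,
            })
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(out_dir / "fits.csv", index=False)
    summary["median_width_by_class"] = {
        cls: float(np.median([f.width_w for f in fits[cls]]))
        for cls in LUMINANCE_CLASSES
    }

    stage("popmodel")
    rates_equi, sub_equi = _class_block(pop, table, "equi")
    grid = popmodel.run_grid(
        rates_equi, sub_equi, widths=cfg.grid_widths,
        fractions=cfg.grid_fractions, bias_family=cfg.bias_family,
        iterations=cfg.grid_iterations,
        seed=_stage_seed(cfg.seed, "popmodel"),
        n_model=min(cfg.n_neurons, 181),
    )
    grid.to_frame().to_csv(out_dir / "heatmap.csv")
    summary["grid_best_cell"] = {
        "width_deg": grid.best_cell[0], "fraction_uniform": grid.best_cell[1],
        "median_r2": float(np.max(grid.median_r2)),
    }

    stage("luminance")
    cls_of = dict(zip(table["stimulus_id"], table["luminance_class"]))
    sid = np.array([cls_of[s] for s in pop.stimulus_ids])
    masks = {c: sid == c for c in LUMINANCE_CLASSES}
    rates_z = geometry.zscore_rates(pop.rates)
    auc_rows = []
    for comparison in ("equi_vs_low", "high_vs_equi"):
        results = luminance.population_auc(
            rates_z, masks, comparison, n_perm=cfg.n_perm,
            seed=_stage_seed(cfg.seed, f"auc-{comparison}"),
            neuron_ids=[n.neuron_id for n in pop.neurons],
        )
        auc_rows += [asdict(r) for r in results]
    auc_df = pd.DataFrame(auc_rows)
    auc_df.to_csv(out_dir / "auc.csv", index=False)
    summary["auc_significant_fraction"] = {
        comparison: float(auc_df.loc[auc_df.comparison == comparison,
                                     "significant"].mean())
        for comparison in ("equi_vs_low", "high_vs_equi")
    }
    peaks = {cls: np.array([f.peak_alpha for f in fits[cls]])
             for cls in LUMINANCE_CLASSES}
    shift = luminance.peak_shift_bin_test(
        peaks["high"], peaks["equi"], n_boot=min(cfg.n_boot, 500),
        seed=_stage_seed(cfg.seed, "peakshift"),
    )
    pd.DataFrame(
        [{"bin": b, "p_mean": v[0], "ci_lo": v[1][0], "ci_hi": v[1][1],
          "n_cells": v[2]} for b, v in shift.items()]
    ).to_csv(out_dir / "peakshift.csv", index=False)

    stage("geometry")
    rsa = {}
    for cls in LUMINANCE_CLASSES:
        rates, sub = _class_block(pop, table, cls)
        nrdm = geometry.neural_rdm(rates, labels=list(sub["stimulus_id"]))
        href = geometry.hue_angle_rdm(sub)
        r, p = geometry.rsa_correlation(nrdm, href)
        rsa[cls] = {"r": r, "p": p}
    summary["rsa_vs_hue"] = rsa
    rates, sub = _class_block(pop, table, "equi")
    emb = geometry.sammon_mds(
        geometry.neural_rdm(rates, labels=list(sub["stimulus_id"])),
        k=cfg.mds_dim, n_restarts=cfg.mds_restarts,
        seed=_stage_seed(cfg.seed, "mds"),
    )
    emb_df = pd.DataFrame(emb.coords,
                          columns=[f"dim{i+1}" for i in range(cfg.mds_dim)])
    emb_df.insert(0, "stimulus_id", list(sub["stimulus_id"]))
    emb_df.to_csv(out_dir / "embedding.csv", index=False)
    (out_dir / "embedding.json").write_text(
        json.dumps({"stress": emb.stress, "k": emb.k,
                    "n_restarts": emb.n_restarts}))
    summary["mds_stress"] = emb.stress

    if cfg.run_decoding:
        stage("decoding")
        tensor, _ = decoding.hue_matched_tensor(pop, table)
        dec = {}
        for cls in LUMINANCE_CLASSES:
            acc, _ = decoding.hue_generalization(tensor, cls)
            dec[f"hue_gen_to_{cls}"] = acc
        for a, b in (("low", "equi"), ("equi", "high"), ("low", "high")):
            acc, _ = decoding.luminance_generalization(tensor, a, b)
            dec[f"lum_{a}_vs_{b}"] = acc
        summary["decoding_accuracy"] = dec
        (out_dir / "decoding.json").write_text(json.dumps(dec, indent=2))

    stage("selectivity")
    trip = table.dropna(subset=["triplet_id"])
    sel_rates = {}
    for cls in ("low", "high"):
        ids = trip.loc[trip.luminance_class == cls, "stimulus_id"]
        idx = [pop.stimulus_ids.index(s) for s in ids]
        sel_rates[cls] = pop.rates[:, idx]
    summaries = selectivity.summarize_population(
        sel_rates["low"], sel_rates["high"],
        neuron_ids=[n.neuron_id for n in pop.neurons],
    )
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out_dir / "selectivity.csv", index=False)
    cats = pd.Series([s.category for s in summaries]).value_counts()
    summary["selectivity_categories"] = cats.to_dict()
    rates_equi, sub_equi = _class_block(pop, table, "equi")
    eq_peaks = np.array([
        tuning_peak_angle(r, sub_equi["hue_angle_deg"].to_numpy())
        for r in rates_equi
    ])
    p_warm, ci, ratio = selectivity.warm_cool_test(
        eq_peaks, sub_equi["hue_angle_deg"].to_numpy(),
        n_perm=cfg.n_perm, n_boot=min(cfg.n_boot, 500),
        seed=_stage_seed(cfg.seed, "warmcool"),
    )
    summary["warm_cool"] = {"p_mean": p_warm, "ci": ci, "ratio": ratio}

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("bundle written to %s", out_dir)
    return summary
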