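"""End-to-end orchestration over synthetic data.

A single YAML file configures every stage; each stage reads and writes
plain files (CSV/TSV/TIFF/MTX) so any one of them can be run, inspected
or replaced independently, and a JSON manifest records the configuration
hash, seed, package version and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, histone, imaging, metabolomics, sc
from .synthio import SimConfig, io as synth_io
from .synthio.image import gen_aggregate_scenes
from .synthio.metab import gen_metabolomics_table
from .synthio.ms import gen_histone_peak_table
from .synthio.reference import gen_reference_embedding
from .synthio.sc import gen_sc_dataset

__all__ = ["run_pipeline", "ConfigError", "DataError", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("ms", "sc", "image", "metab", "reference")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(RuntimeError):
    """A stage failed on its inputs."""


def _config_hash(raw: dict) -> str:
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages in order and return the manifest."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    stages = raw.pop("stages", list(ALL_STAGES))
    out = Path(out_dir or raw.pop("out", "trophoflux_run"))
    raw.pop("out", None)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stage name(s): {unknown}; valid: {list(ALL_STAGES)}")
    try:
        cfg = SimConfig.from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config_hash": _config_hash(raw | {"stages": stages}),
        "seed": cfg.seed,
        "stages": list(stages),
        "version": __version__,
        "out_dir": str(out),
        "row_counts": {},
        "outputs": {},
    }
    runners = {
        "ms": _run_ms,
        "sc": _run_sc,
        "image": _run_image,
        "metab": _run_metab,
        "reference": _run_reference,
    }
    for stage in stages:
        log.info("running stage %s", stage)
        try:
            counts, outputs = runners[stage](cfg, out / stage)
        except (ValueError, KeyError, RuntimeError) as exc:
            raise DataError(f"stage {stage!r} failed: {exc}") from exc
        manifest["row_counts"][stage] = counts
        manifest["outputs"][stage] = outputs
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_ms(cfg: SimConfig, out: Path):
    table, truth = gen_histone_peak_table(cfg)
    synth_io.write_csv(table, out / "peak_table.csv")
    normalized, factors = histone.spikein_normalize(table)
    deconv = histone.deconvolve_table(normalized)
    abundance = histone.relative_abundance(deconv)
    turnover = histone.turnover_table(deconv, truth["control_samples"])
    synth_io.write_csv(abundance, out / "relative_abundance.csv")
    synth_io.write_csv(turnover, out / "turnover.csv")
    factors.to_csv(out / "spikein_factors.csv")
    return (
        {"peak_table": len(table), "abundance": len(abundance), "turnover": len(turnover)},
        {"peak_table": str(out / "peak_table.csv"), "turnover": str(out / "turnover.csv")},
    )


def _run_sc(cfg: SimConfig, out: Path):
    adata, hto, truth = gen_sc_dataset(cfg)
    synth_io.write_mtx_triplet(adata, out / "counts")
    hto.to_csv(out / "hto_counts.csv")
    demux = sc.hto_demux(hto)
    singlets = demux.index[demux["classification"] == "singlet"]
    filtered, report = sc.qc_filter(adata[adata.obs_names.isin(singlets)].copy())
    expr = sc.log_normalize(filtered)
    maturity = sc.maturity_score(expr)
    per_cell = pd.DataFrame(
        {
            "barcode": expr.obs_names,
            "demux_tag": demux.loc[expr.obs_names, "tag"].to_numpy(),
            "population_truth": expr.obs["population"].to_numpy(),
            "maturity_score": maturity,
        }
    )
    synth_io.write_csv(per_cell, out / "per_cell.csv")
    (out / "qc_report.json").write_text(json.dumps(report, indent=1))
    return (
        {"cells_input": int(adata.n_obs), "singlets": int(len(singlets)), **report},
        {"per_cell": str(out / "per_cell.csv")},
    )


def _run_image(cfg: SimConfig, out: Path):
    scenes = gen_aggregate_scenes(cfg)
    records = []
    for i, (scene, truth) in enumerate(scenes):
        synth_io.write_scene(scene, truth, out, f"aggregate_{i:03d}")
        res = imaging.apical_polarity_ratio(scene, aggregate_id=i)
        layers = imaging.classify_outer_inner(scene)
        acc = np.mean([layers[lab] == truth["layers"][lab] for lab in layers])
        records.append(
            {
                "aggregate": i,
                "apical_ratio": res.ratio,
                "true_enrichment": truth["apical_enrichment"],
                "layer_accuracy": float(acc),
            }
        )
    df = pd.DataFrame(records)
    synth_io.write_csv(df, out / "polarity.csv")
    return ({"aggregates": len(df)}, {"polarity": str(out / "polarity.csv")})


def _run_metab(cfg: SimConfig, out: Path):
    tables, truth = gen_metabolomics_table(cfg)
    synth_io.write_csv(tables["analytes"], out / "areas.csv")
    normalized = metabolomics.is_normalize(
        tables["analytes"], tables["is_map"], tables["internal_standards"]
    )
    calibrated, curves = metabolomics.calibrate_concentrations(normalized, tables["standards"])
    per_protein = metabolomics.protein_normalize(calibrated, tables["protein"])
    diff = metabolomics.differential_metabolites(per_protein, control_group=cfg.metab.groups[0])
    synth_io.write_csv(calibrated, out / "concentrations.csv")
    synth_io.write_csv(diff, out / "differential.csv")
    return (
        {"areas": len(tables["analytes"]), "differential": len(diff)},
        {"differential": str(out / "differential.csv")},
    )


def _run_reference(cfg: SimConfig, out: Path):
    emb = gen_reference_embedding(cfg)
    q_labels = sc.nhood_stage_knn(emb.ref_points, emb.ref_labels, emb.query_points, k=3)
    multisets = [[q_labels[i] for i in m] for m in emb.memberships]
    final = sc.consolidate_labels(multisets, stage_order=cfg.reference.stages)
    df = pd.DataFrame(
        {
            "cell": range(len(final)),
            "final_label": final,
            "truth": emb.cell_truth,
        }
    )
    synth_io.write_csv(df, out / "stage_labels.csv")
    return ({"cells": len(df)}, {"stage_labels": str(out / "stage_labels.csv")})
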