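"""Synthetic targeted-metabolomics peak tables with known concentrations.

Analyte peak area = concentration x analyte response slope x per-sample
material factor x lognormal noise; the internal standard of each analyte
is spiked at a fixed amount, so its area carries the same sample factor
and noise — dividing analyte by IS removes the factor. The dilution
series is measured at sample factor 1 with the same noise model. The
``protein_confound`` knob multiplies both the treated samples' material
and their protein content, a cell-amount artifact that protein
normalization is meant to cancel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = ["gen_metabolomics_table"]


def _lognoise(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-(sigma**2) / 2, sigma, size=size)


def gen_metabolomics_table(config: SimConfig) -> tuple[dict, dict]:
    """Generate peak tables and ground truth.

    Returns ``(tables, truth)``. ``tables`` holds the tidy analyte table
    (sample, group, analyte, area), the internal-standard areas
    (sample, standard, area), the dilution-series standards
    (analyte, concentration, area — already IS-normalized scale), the
    analyte -> IS map and per-sample protein content. ``truth`` records
    concentrations, fold changes, slopes and sample factors.
    """
    cfg = config.metab
    rng = config.rng("metab")
    analytes = [f"analyte_{i + 1:03d}" for i in range(cfg.n_analytes)]
    is_map = {a: f"IS_{i % max(cfg.n_analytes // 4, 1) + 1}" for i, a in enumerate(analytes)}
    standards_ids = sorted(set(is_map.values()))

    control, treated = cfg.groups
    samples = [f"{control}_{i + 1}" for i in range(cfg.n_per_group)] + [
        f"{treated}_{i + 1}" for i in range(cfg.n_per_group)
    ]
    group_of = {s: control if s.startswith(control) else treated for s in samples}

    if np.isscalar(cfg.fold_changes):
        fcs = np.full(cfg.n_analytes, float(cfg.fold_changes))
    else:
        fcs = np.asarray(cfg.fold_changes, dtype=float)
        if fcs.size != cfg.n_analytes:
            raise ValueError("fold_changes length must equal n_analytes")

    base_conc = cfg.base_concentration * rng.lognormal(0.0, 0.3, cfg.n_analytes)
    slopes = rng.lognormal(np.log(1e4), 0.3, cfg.n_analytes)
    is_amount = 1.0
    is_slope = {sid: float(rng.lognormal(np.log(1e4), 0.3)) for sid in standards_ids}

    factors = _lognoise(rng, cfg.sample_factor_cv, len(samples))
    confound = np.array(
        [cfg.protein_confound if group_of[s] == treated else 1.0 for s in samples]
    )
    factors = factors * confound
    protein = cfg.protein_mean_ug * _lognoise(rng, cfg.protein_cv, len(samples)) * confound

    rows, is_rows = [], []
    conc_truth = np.empty((len(samples), cfg.n_analytes))
    for si, s in enumerate(samples):
        conc = base_conc * np.where(group_of[s] == treated, fcs, 1.0)
        conc_truth[si] = conc
        noise = _lognoise(rng, cfg.noise_cv, cfg.n_analytes)
        areas = conc * slopes * factors[si] * noise
        for a, area in zip(analytes, areas):
            rows.append({"sample": s, "group": group_of[s], "analyte": a, "area": float(area)})
        for sid in standards_ids:
            n = _lognoise(rng, cfg.noise_cv, 1)[0]
            is_rows.append(
                {"sample": s, "standard": sid, "area": float(is_amount * is_slope[sid] * factors[si] * n)}
            )

    std_rows = []
    for ai, a in enumerate(analytes):
        for level in cfg.dilution_levels:
            n = _lognoise(rng, cfg.noise_cv, 1)[0]
            # dilution series measured on the IS-normalized scale
            area = level * slopes[ai] / (is_amount * is_slope[is_map[a]]) * n
            std_rows.append({"analyte": a, "concentration": float(level), "area": float(area)})

    tables = {
        "analytes": pd.DataFrame(rows),
        "internal_standards": pd.DataFrame(is_rows),
        "standards": pd.DataFrame(std_rows),
        "is_map": is_map,
        "protein": dict(zip(samples, protein)),
    }
    truth = {
        "concentrations": pd.DataFrame(conc_truth, index=samples, columns=analytes),
        "fold_changes": dict(zip(analytes, fcs)),
        "slopes": dict(zip(analytes, slopes)),
        "sample_factors": dict(zip(samples, factors)),
        "base_concentration": dict(zip(analytes, base_conc)),
    }
    return tables, truth
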