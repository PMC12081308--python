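"""Synthetic hashed droplet scRNA-seq data with per-cell ground truth.

RNA counts are gamma-Poisson (negative binomial with fixed dispersion)
around lognormal gene-level means. The gene universe always contains the
built-in pTE/mTE signature genes and a block of "MT-" mitochondrial genes;
population identity enters only through log-mean shifts (delta) on
signature genes, so delta = 0 makes populations indistinguishable by
construction. Mitochondrial content is drawn per cell from a Beta
distribution and allocated to the MT- block. Each population carries one
dominant hashtag; doublets sum the RNA of two cells from (possibly
different) populations and carry both dominant tags.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from ..sc import load_builtin_signatures
from .config import SimConfig

__all__ = ["gen_sc_dataset"]


def _gene_universe(cfg) -> tuple[list[str], dict[str, list[str]]]:
    signatures = {name: list(sig.genes) for name, sig in load_builtin_signatures().items()}
    for name, genes in cfg.extra_signatures.items():
        signatures[name] = list(genes)
    named = [g for genes in signatures.values() for g in genes]
    if len(set(named)) != len(named):
        named = list(dict.fromkeys(named))
    mito = [f"MT-SIM{i + 1}" for i in range(cfg.n_mito_genes)]
    n_filler = cfg.n_genes - len(named) - len(mito)
    if n_filler < 0:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for {len(named)} signature genes "
            f"and {len(mito)} mitochondrial genes"
        )
    filler = [f"GENE{i + 1:05d}" for i in range(n_filler)]
    genes = named + filler + mito
    for name, sig_genes in signatures.items():
        absent = set(sig_genes) - set(genes)
        if absent:
            raise ValueError(f"signature {name} genes absent from universe: {sorted(absent)}")
    return genes, signatures


def gen_sc_dataset(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Generate (RNA counts AnnData, HTO tags x cells DataFrame, truth).

    The AnnData is cells x genes with integer counts; truth has one row
    per barcode with its population, sample tag, doublet status, true
    mitochondrial fraction and the per-gene expected means stored in
    ``adata.var["true_mean"]`` (averaged over the generated cells).
    """
    cfg = config.sc
    rng = config.rng("sc")
    genes, signatures = _gene_universe(cfg)
    n_genes = len(genes)
    mito_mask = np.array([g.startswith("MT-") for g in genes])
    gene_index = {g: j for j, g in enumerate(genes)}

    # gene-level lognormal weights shared by all populations
    base_w = rng.lognormal(0.0, 1.0, size=n_genes)
    base_w[mito_mask] = 0.0

    pop_means = {}
    for pop in cfg.populations:
        w = base_w.copy()
        for sig_name, delta in pop.shifts.items():
            if sig_name not in signatures:
                raise ValueError(f"population {pop.name}: unknown signature {sig_name!r}")
            cols = [gene_index[g] for g in signatures[sig_name]]
            w[cols] = w[cols] * np.exp(delta)
        pop_means[pop.name] = w / w.sum()  # relative expression program

    n_singlets = sum(p.n_cells for p in cfg.populations)
    pop_of = np.repeat([p.name for p in cfg.populations], [p.n_cells for p in cfg.populations])
    tag_of = np.repeat([p.tag for p in cfg.populations], [p.n_cells for p in cfg.populations])

    depth = cfg.mean_depth * _lognormal_cv(rng, cfg.depth_cv, n_singlets)
    mito_frac = rng.beta(*cfg.mito_beta, size=n_singlets)

    # per-cell mean matrix: non-mito program scaled to (1 - p) of depth,
    # mito block sharing p of depth equally
    mu = np.empty((n_singlets, n_genes))
    for name, program in pop_means.items():
        sel = pop_of == name
        mu[sel] = np.outer(depth[sel] * (1 - mito_frac[sel]), program)
    mu[:, mito_mask] = (depth * mito_frac)[:, None] / max(mito_mask.sum(), 1)

    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    tags = sorted({p.tag for p in cfg.populations})
    hto = rng.poisson(cfg.ambient_hto_mean, size=(len(tags), n_singlets)).astype(np.int64)
    tag_row = {t: i for i, t in enumerate(tags)}
    dominant = rng.poisson(cfg.ambient_hto_mean * cfg.dominant_multiplier, size=n_singlets)
    hto[[tag_row[t] for t in tag_of], np.arange(n_singlets)] += dominant

    # doublets: replace pairs of singlets' droplets with merged droplets
    n_doublets = int(round(cfg.doublet_rate * n_singlets / (1 + cfg.doublet_rate)))
    records = []
    barcodes = []
    if n_doublets > 0:
        pair_idx = rng.choice(n_singlets, size=(n_doublets, 2), replace=False)
        merged_counts = counts[pair_idx[:, 0]] + counts[pair_idx[:, 1]]
        merged_hto = hto[:, pair_idx[:, 0]] + hto[:, pair_idx[:, 1]]
        used = set(pair_idx.ravel().tolist())
    else:
        pair_idx = np.empty((0, 2), dtype=int)
        merged_counts = np.empty((0, n_genes), dtype=np.int32)
        merged_hto = np.empty((len(tags), 0), dtype=np.int64)
        used = set()

    keep = np.array([i for i in range(n_singlets) if i not in used])
    singlet_counts = counts[keep]
    singlet_hto = hto[:, keep]

    for j, i in enumerate(keep):
        barcodes.append(f"CELL{j + 1:06d}")
        records.append(
            {
                "barcode": barcodes[-1],
                "population": pop_of[i],
                "tag": tag_of[i],
                "is_doublet": False,
                "true_mito_fraction": float(mito_frac[i]),
                "true_depth": float(depth[i]),
            }
        )
    for d in range(n_doublets):
        bc = f"DBLT{d + 1:06d}"
        barcodes.append(bc)
        i, j = pair_idx[d]
        records.append(
            {
                "barcode": bc,
                "population": f"{pop_of[i]}+{pop_of[j]}",
                "tag": f"{tag_of[i]}+{tag_of[j]}",
                "is_doublet": True,
                "true_mito_fraction": float((mito_frac[i] + mito_frac[j]) / 2),
                "true_depth": float(depth[i] + depth[j]),
            }
        )

    all_counts = np.vstack([singlet_counts, merged_counts])
    all_hto = np.hstack([singlet_hto, merged_hto])

    adata = ad.AnnData(
        X=all_counts,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.var["mito"] = mito_mask
    adata.var["true_mean"] = mu.mean(axis=0)
    truth = pd.DataFrame.from_records(records).set_index("barcode")
    adata.obs = adata.obs.join(truth)
    hto_df = pd.DataFrame(all_hto, index=pd.Index(tags, name="tag"), columns=barcodes)
    return adata, hto_df, truth


def _lognormal_cv(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-(sigma**2) / 2, sigma, size=size)
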