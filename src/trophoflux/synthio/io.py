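"""Plain-format writers for the synthetic datasets.

Counts go out as a CellRanger-style MTX triplet (matrix.mtx, genes.tsv,
barcodes.tsv), HTO counts and tidy tables as CSV, image channels and
label masks as 16-bit TIFF, and scene truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from ..imaging import AggregateScene

__all__ = ["write_mtx_triplet", "write_scene", "write_csv"]


def write_mtx_triplet(adata, outdir: str | Path) -> Path:
    """Write genes x cells MTX + genes.tsv + barcodes.tsv (CellRanger dialect)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    mat = sp.csc_matrix(x.T if not sp.issparse(x) else x.T)  # genes x cells
    scipy.io.mmwrite(outdir / "matrix.mtx", mat.astype(int))
    genes = pd.DataFrame({"id": adata.var_names, "symbol": adata.var_names})
    genes.to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    return outdir


def write_scene(scene: AggregateScene, truth: dict, outdir: str | Path, stem: str) -> Path:
    """16-bit TIFFs per channel + label/aggregate masks + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in scene.channels.items():
        scaled = np.clip(img, 0, None)
        peak = scaled.max()
        if peak > 0:
            scaled = scaled / peak * 60000.0
        tifffile.imwrite(outdir / f"{stem}_{name}.tif", scaled.astype(np.uint16))
    tifffile.imwrite(outdir / f"{stem}_nuclei.tif", scene.nuclei.astype(np.uint16))
    tifffile.imwrite(outdir / f"{stem}_aggregate.tif", scene.mask().astype(np.uint16))
    side = {
        k: v for k, v in truth.items() if not isinstance(v, np.ndarray)
    } | {"layers": {str(k): v for k, v in truth["layers"].items()}}
    (outdir / f"{stem}_truth.json").write_text(json.dumps(side, indent=1, default=float))
    return outdir


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
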