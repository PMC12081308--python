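"""Single-cell stage analysis: QC, normalization, hashtag demultiplexing,
module scoring, the polar-minus-mural TE maturity statistic and
developmental-stage label consolidation.

RNA counts live in an :class:`anndata.AnnData` (cells x genes); hashtag
(HTO) counts in a tags x cells :class:`pandas.DataFrame`.

The maturity statistic contrasts two built-in 25-gene signatures: polar
trophectoderm (pTE, the NR2F2 expression module) and mural trophectoderm
(mTE, genes co-expressed with CDX2/S100A13/S100A16/ATP6V0A4). A cell's TE
maturity is its pTE module score minus its mTE module score, so polar-like
cells score positive and mural-like cells negative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

__all__ = [
    "GeneSignature",
    "load_builtin_signatures",
    "qc_filter",
    "log_normalize",
    "clr_normalize",
    "hto_demux",
    "module_score",
    "maturity_score",
    "nhood_stage_knn",
    "consolidate_labels",
    "DEFAULT_STAGE_ORDER",
]

log = logging.getLogger(__name__)

DEFAULT_STAGE_ORDER: tuple[str, ...] = ("E5", "E6", "E7", "E8", "E9", "CS7")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with module-scoring parameters."""

    name: str
    genes: tuple[str, ...]
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        genes = tuple(g.strip() for g in self.genes)
        if not genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(genes)) != len(genes):
            raise ValueError("signature genes must be unique")
        object.__setattr__(self, "genes", genes)


def load_builtin_signatures() -> dict[str, GeneSignature]:
    """The two built-in 25-gene TE signatures (pTE and mTE)."""
    path = resources.files("trophoflux.data").joinpath("te_signatures.csv")
    table = pd.read_csv(path)
    return {
        name: GeneSignature(name=name, genes=tuple(grp["gene"]))
        for name, grp in table.groupby("set", sort=False)
    }


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def qc_filter(
    adata: ad.AnnData,
    mito_max: float = 0.15,
    umi_min: int = 7000,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, dict[str, int]]:
    """Drop cells with high mitochondrial fraction or low UMI depth.

    Retains cells with mitochondrial count fraction <= ``mito_max`` AND
    total counts >= ``umi_min`` (defaults 15% and 7,000; a 5,000 UMI floor
    is appropriate for shallower runs). Returns the filtered matrix and a
    report of removals per criterion. If no gene matches ``mito_prefix``
    the mitochondrial criterion is skipped with a warning.
    """
    counts = _dense(adata.X)
    total = counts.sum(axis=1)
    mito_mask = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    if mito_mask.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, counts[:, mito_mask].sum(axis=1) / total, 0.0)
        pass_mito = mito_frac <= mito_max
    else:
        log.warning("no genes with prefix %r; mitochondrial criterion skipped", mito_prefix)
        pass_mito = np.ones(adata.n_obs, dtype=bool)
    pass_umi = total >= umi_min
    keep = pass_mito & pass_umi
    report = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "n_failed_mito": int((~pass_mito).sum()),
        "n_failed_umi": int((~pass_umi).sum()),
    }
    return adata[keep].copy(), report


def log_normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: ``ln(1 + scale * count / cell_total)``."""
    counts = _dense(adata.X).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("all-zero cell encountered; run qc_filter first")
    out = adata.copy()
    out.X = np.log1p(scale * counts / totals)
    return out


def clr_normalize(hto: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform per cell: ``ln(x+1) - mean_tags ln(x+1)``."""
    if hto.shape[0] < 2:
        raise ValueError("CLR needs at least two tags")
    logged = np.log1p(hto.to_numpy(dtype=float))
    clr = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=hto.index, columns=hto.columns)


def hto_demux(hto: pd.DataFrame, c: float = 3.0, random_state: int = 0) -> pd.DataFrame:
    """Classify each cell as singlet (with tag), doublet or negative.

    For each tag, CLR-transformed counts are split into background and
    positive groups by 1D 2-means; a cell is positive for the tag if its
    log tag count exceeds ``mean + c * sd`` of the background group's log
    counts. (Thresholding on raw counts rather than on the CLR values
    keeps ambient-only cells negative: their CLR sits near zero, above the
    strongly negative CLR of cells dominant in another tag, but their
    counts stay at the ambient level.) Cells positive for exactly one tag
    are singlets of that tag, for two or more doublets, for none
    negatives. This is a transparent approximation of cluster-based
    hashtag demultiplexers; it assumes a bimodal distribution per tag.
    """
    clr = clr_normalize(hto)
    n_cells = clr.shape[1]
    positive = np.zeros((clr.shape[0], n_cells), dtype=bool)
    for i, tag in enumerate(clr.index):
        values = clr.loc[tag].to_numpy()
        log_counts = np.log1p(hto.loc[tag].to_numpy(dtype=float))
        if np.ptp(values) == 0:
            log.warning("tag %s has constant counts; skipped", tag)
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
        groups = km.fit_predict(values.reshape(-1, 1))
        bg = int(np.argmin(km.cluster_centers_.ravel()))
        bg_log_counts = log_counts[groups == bg]
        threshold = bg_log_counts.mean() + c * bg_log_counts.std()
        positive[i] = log_counts > threshold
    n_pos = positive.sum(axis=0)
    classification = np.where(n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet"))
    top_tag = clr.index.to_numpy()[np.argmax(positive, axis=0)]
    tag = np.where(n_pos == 1, top_tag, "")
    return pd.DataFrame(
        {"classification": classification, "tag": tag}, index=clr.columns
    )


def module_score(expr: ad.AnnData, sig: GeneSignature) -> np.ndarray:
    """Per-cell gene-set score against expression-matched controls.

    Genes are ranked by mean expression across cells and cut into
    ``sig.n_bins`` equal-frequency bins; for each signature gene,
    ``sig.n_ctrl`` control genes are drawn with replacement from its bin
    using ``sig.seed``. The score is the mean expression of the signature
    genes minus the mean expression of the pooled control draws, so a
    random gene set scores zero in expectation. Signature genes are
    processed in sorted order, making the score invariant to the order the
    signature lists them in.
    """
    present = [g for g in sig.genes if g in expr.var_names]
    missing = set(sig.genes) - set(present)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    if missing:
        log.warning("signature %s: %d gene(s) absent, dropped", sig.name, len(missing))
    x = _dense(expr.X)
    gene_means = x.mean(axis=0)
    ranks = pd.Series(gene_means, index=expr.var_names).rank(method="first")
    bins = pd.qcut(ranks, min(sig.n_bins, len(ranks)), labels=False)
    rng = np.random.default_rng(sig.seed)
    gene_index = {g: j for j, g in enumerate(expr.var_names)}
    sig_cols = [gene_index[g] for g in sorted(present)]
    ctrl_cols: list[int] = []
    by_bin = {b: np.flatnonzero(bins.to_numpy() == b) for b in np.unique(bins)}
    for g in sorted(present):
        pool = by_bin[bins[g]]
        ctrl_cols.extend(rng.choice(pool, size=sig.n_ctrl, replace=True))
    return x[:, sig_cols].mean(axis=1) - x[:, ctrl_cols].mean(axis=1)


def maturity_score(expr: ad.AnnData) -> np.ndarray:
    """TE maturity: pTE module score minus mTE module score per cell."""
    sigs = load_builtin_signatures()
    return module_score(expr, sigs["pTE"]) - module_score(expr, sigs["mTE"])


def nhood_stage_knn(
    ref_points: np.ndarray,
    ref_labels: Sequence[str],
    queries: np.ndarray,
    k: int = 3,
) -> list[str]:
    """Assign each query the modal stage label of its k nearest references.

    Euclidean distance in the 2D embedding; ties in the vote fall back to
    the label of the single nearest neighbor; equidistant reference points
    are taken in reference order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref_points = np.asarray(ref_points, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    ref_labels = list(ref_labels)
    if len(ref_points) < k:
        raise ValueError(f"reference has {len(ref_points)} points; k={k}")
    out = []
    for q in queries:
        d = np.linalg.norm(ref_points - q, axis=1)
        order = np.argsort(d, kind="stable")[:k]
        votes = Counter(ref_labels[i] for i in order)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out.append(ref_labels[order[0]])
        else:
            out.append(top[0][0])
    return out


def consolidate_labels(
    label_multisets: Iterable[Iterable[str]],
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
) -> list[str]:
    """Collapse each cell's multiset of neighborhood stage labels to one label.

    A label held by more than half the entries wins; exactly two labels at
    exactly half each give a composite like ``"E6/E7"`` (in developmental
    order); an empty multiset is ``"unassigned"``; everything else is
    ``"ambiguous"``.
    """
    rank = {s: i for i, s in enumerate(stage_order)}
    out = []
    for labels in label_multisets:
        counts = Counter(labels)
        total = sum(counts.values())
        if total == 0:
            out.append("unassigned")
            continue
        (top_label, top_n), *rest = counts.most_common()
        if 2 * top_n > total:
            out.append(top_label)
        elif len(counts) == 2 and 2 * top_n == total:
            a, b = sorted(counts, key=lambda s: (rank.get(s, len(rank)), s))
            out.append(f"{a}/{b}")
        else:
            out.append("ambiguous")
    return out
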