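"""Histone-PTM quantification from Skyline-style MS1/MS2 peak tables.

Four stages, each a pure function over a tidy :class:`pandas.DataFrame`
peak table:

1. :func:`spikein_normalize` — remove per-sample instrument variation using
   heavy arginine-labelled spike-in standards present at equal concentration
   in every sample.
2. :func:`isobaric_deconvolution` — split a coeluting isobaric MS1 peak
   (e.g. H3K36me3 vs H3K27me2K36me1) between species according to the
   averaged integrals of species-unique MS2 fragment ions.
3. :func:`relative_abundance` — express each peptidoform as a percentage of
   the summed MS1 area of all forms sharing its peptide backbone.
4. :func:`label_incorporation` — the 13C-glucose acetylation-turnover
   statistic: a heavy acetyl group shifts the precursor by +2 Da, so after
   subtracting the natural-abundance M2 expected from the observed M
   (ratio taken from unlabelled control samples), the de novo fraction is
   100 * M2' / (M2' + M).

Peak-table columns: ``sample``, ``peptide``, ``mods``, ``charge``,
``ms_level`` (1 or 2), ``isotopologue`` (0 for M, 1 for M1, ...; MS2 rows
use 0), ``fragment_id`` (MS2 rows only), ``area``, ``heavy_flag``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "MissingStandardError",
    "spikein_normalize",
    "relative_abundance",
    "isobaric_deconvolution",
    "label_incorporation",
    "LabelIncorporationResult",
    "DEFAULT_ISOBARIC_PAIRS",
]

log = logging.getLogger(__name__)

PEAK_TABLE_COLUMNS = [
    "sample",
    "peptide",
    "mods",
    "charge",
    "ms_level",
    "isotopologue",
    "fragment_id",
    "area",
    "heavy_flag",
]

# Isobaric species pairs resolved by unique MS2 fragments, keyed by the
# modification-string dialect. H3K36me3 and H3K27me2K36me1 coelute at the
# same precursor mass (3 vs 2+1 methyls on the K27-R40 peptide).
DEFAULT_ISOBARIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("K36me3", "K27me2;K36me1"),
)

_FORM_KEY = ["peptide", "mods", "charge"]


class MissingStandardError(ValueError):
    """A sample lacks one of the heavy spike-in standards."""


def _check_columns(t: pd.DataFrame) -> None:
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")


def spikein_normalize(t: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide every area by its sample's spike-in factor.

    The factor for a sample is the median, over heavy standards, of that
    standard's area in the sample divided by the standard's geometric mean
    across all samples. The geometric mean is a scale-free anchor, the
    median is robust to one aberrant standard, and because standards are
    divided too the operation is idempotent.

    Returns the normalized table and the per-sample factors.
    """
    _check_columns(t)
    heavy = t[t["heavy_flag"].astype(bool) & (t["ms_level"] == 1)]
    if heavy.empty:
        raise MissingStandardError("no heavy-standard rows in peak table")
    samples = t["sample"].unique()
    # total MS1 area per (sample, standard)
    std_area = (
        heavy.groupby(["sample", "peptide", "mods"], sort=False)["area"].sum().unstack(["peptide", "mods"])
    )
    std_area = std_area.reindex(samples)
    for col in std_area.columns:
        bad = std_area[col].isna() | (std_area[col] <= 0)
        if bad.any():
            raise MissingStandardError(
                f"heavy standard {col} missing or non-positive in samples "
                f"{list(std_area.index[bad])}"
            )
    geo_mean = np.exp(np.log(std_area).mean(axis=0))
    # median taken in log space: factors are multiplicative, so with an even
    # number of standards the central pair averages geometrically ({2, 8} -> 4)
    factors = np.exp(np.log(std_area / geo_mean).median(axis=1))
    factors.name = "spikein_factor"
    log.info("spike-in factors: %s", factors.to_dict())
    out = t.copy()
    out["area"] = out["area"] / out["sample"].map(factors).to_numpy()
    return out, factors


def relative_abundance(t: pd.DataFrame) -> pd.DataFrame:
    """Percent of each peptidoform within its peptide backbone, per sample.

    Uses summed MS1 areas over the isotopologue envelope; heavy standards
    are excluded. Backbones with zero total area yield missing percentages
    rather than zeros. Percentages per (sample, backbone) sum to 100.
    """
    _check_columns(t)
    endo = t[(t["ms_level"] == 1) & ~t["heavy_flag"].astype(bool)]
    form = (
        endo.groupby(["sample", *_FORM_KEY], sort=False)["area"].sum().reset_index(name="area")
    )
    totals = form.groupby(["sample", "peptide"], sort=False)["area"].transform("sum")
    form["percent"] = np.where(totals > 0, 100.0 * form["area"] / totals, np.nan)
    return form.drop(columns="area")


def isobaric_deconvolution(
    ms1_area: float,
    fragment_areas: Mapping[str, Sequence[float]],
    min_fragments: int = 3,
) -> dict[str, float] | None:
    """Split an isobaric MS1 area between species by mean MS2 fragment area.

    ``share_i = mean(fragments_i) / sum_j mean(fragments_j)``; returned
    areas are ``share_i * ms1_area`` and conserve the MS1 area exactly.
    Returns None (unresolved) when every species' fragments are zero —
    never an even split.
    """
    if ms1_area < 0:
        raise ValueError("ms1_area must be >= 0")
    if len(fragment_areas) < 2:
        raise ValueError("need at least two species to deconvolve")
    means = {}
    for species, frags in fragment_areas.items():
        frags = np.asarray(list(frags), dtype=float)
        if frags.size == 0:
            raise ValueError(f"species {species!r} has no fragment areas")
        if frags.size < min_fragments:
            log.warning(
                "species %s has %d fragment(s); %d expected", species, frags.size, min_fragments
            )
        means[species] = float(frags.mean())
    total = sum(means.values())
    if total == 0:
        log.warning("all fragment means zero; isobaric peak unresolved")
        return None
    shares = {sp: m / total for sp, m in means.items()}
    # distribute so the areas sum to ms1_area exactly despite rounding
    out = {sp: share * ms1_area for sp, share in shares.items()}
    return out


def deconvolve_table(
    t: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_ISOBARIC_PAIRS,
    min_fragments: int = 3,
) -> pd.DataFrame:
    """Apply isobaric deconvolution to every configured pair in a peak table.

    For each (sample, peptide, charge) where both species of a pair occur,
    the pair's shared MS1 envelope (stored under the first species) is split
    by that sample's MS2 fragment evidence; each isotopologue area is scaled
    by the species share so the envelope shape is preserved.
    """
    _check_columns(t)
    out = t.copy()
    for sp_a, sp_b in pairs:
        ms1_mask = (out["ms_level"] == 1) & (out["mods"] == sp_a) & ~out["heavy_flag"].astype(bool)
        for (sample, peptide, charge), idx in out[ms1_mask].groupby(
            ["sample", "peptide", "charge"], sort=False
        ).groups.items():
            frag = out[
                (out["ms_level"] == 2)
                & (out["sample"] == sample)
                & (out["peptide"] == peptide)
                & (out["charge"] == charge)
                & (out["mods"].isin([sp_a, sp_b]))
            ]
            if frag.empty or set(frag["mods"]) != {sp_a, sp_b}:
                continue
            fragment_areas = {
                sp: frag.loc[frag["mods"] == sp, "area"].to_numpy() for sp in (sp_a, sp_b)
            }
            env = out.loc[idx]
            split = isobaric_deconvolution(
                float(env["area"].sum()), fragment_areas, min_fragments
            )
            if split is None:
                out.loc[idx, "area"] = np.nan
                continue
            share_a = split[sp_a] / env["area"].sum() if env["area"].sum() > 0 else 0.0
            new_rows = env.copy()
            new_rows["mods"] = sp_b
            new_rows["area"] = env["area"] * (1.0 - share_a)
            out.loc[idx, "area"] = env["area"] * share_a
            out = pd.concat([out, new_rows], ignore_index=True)
    return out


@dataclass(frozen=True)
class LabelIncorporationResult:
    """Per-replicate and mean de novo acetylation percentages."""

    rho: float  # natural M2/M ratio from control samples
    corrected_m2: np.ndarray  # per treated replicate, after clipping at 0
    de_novo_percent: np.ndarray
    mean_percent: float
    n_clipped: int


def label_incorporation(
    control: Sequence[Sequence[float]],
    treated: Sequence[Sequence[float]],
) -> LabelIncorporationResult:
    """De novo acetylation percentage from +2 Da precursor incorporation.

    ``control`` and ``treated`` are lists of isotopologue envelopes
    (areas for M, M1, M2, ...). The natural ratio ``rho`` is the mean of
    per-replicate control M2/M ratios; each treated replicate's M2 is
    corrected to ``M2' = max(0, M2 - rho * M)`` and the de novo percent is
    ``100 * M2' / (M2' + M)``. Meaningful only for singly acetylated
    peptidoforms, where one 13C2-acetyl gives exactly +2 Da.
    """
    control = [np.asarray(e, dtype=float) for e in control]
    treated = [np.asarray(e, dtype=float) for e in treated]
    if not control or not treated:
        raise ValueError("need at least one control and one treated envelope")
    for env in (*control, *treated):
        if env.size < 3:
            raise ValueError("envelope must contain at least M, M1, M2")
    m_c = np.array([e[0] for e in control])
    if np.any(m_c == 0):
        raise ValueError("control envelope has M = 0; natural ratio undefined")
    rho = float(np.mean([e[2] / e[0] for e in control]))
    m_t = np.array([e[0] for e in treated])
    m2_t = np.array([e[2] for e in treated])
    corrected = m2_t - rho * m_t
    n_clipped = int(np.sum(corrected < 0))
    if n_clipped:
        log.info("clipped %d negative corrected M2 value(s) to 0", n_clipped)
    corrected = np.clip(corrected, 0.0, None)
    denom = corrected + m_t
    percent = np.where(denom > 0, 100.0 * corrected / denom, np.nan)
    return LabelIncorporationResult(
        rho=rho,
        corrected_m2=corrected,
        de_novo_percent=percent,
        mean_percent=float(np.nanmean(percent)),
        n_clipped=n_clipped,
    )


def turnover_table(t: pd.DataFrame, control_samples: Sequence[str]) -> pd.DataFrame:
    """Run :func:`label_incorporation` for every singly acetylated peptidoform.

    ``control_samples`` are the unlabelled samples defining the natural
    envelope; all other samples are treated as labelled. Non-singly
    acetylated forms are skipped with a warning. Returns one row per
    (peptidoform, treated sample).
    """
    _check_columns(t)
    endo = t[(t["ms_level"] == 1) & ~t["heavy_flag"].astype(bool)]
    control_set = set(control_samples)
    records = []
    for (peptide, mods, charge), grp in endo.groupby(_FORM_KEY, sort=False):
        n_ac = mods.count("ac")
        if n_ac != 1:
            if n_ac > 1:
                log.warning("skipping %s %s: not singly acetylated", peptide, mods)
            continue
        env = grp.pivot_table(index="sample", columns="isotopologue", values="area", aggfunc="sum")
        if env.shape[1] < 3:
            continue
        env = env.reindex(columns=range(int(env.columns.max()) + 1), fill_value=0.0)
        ctrl = env.loc[env.index.isin(control_set)]
        trt = env.loc[~env.index.isin(control_set)]
        if ctrl.empty or trt.empty:
            continue
        res = label_incorporation(ctrl.to_numpy(), trt.to_numpy())
        for sample, pct, m2c in zip(trt.index, res.de_novo_percent, res.corrected_m2):
            records.append(
                {
                    "peptide": peptide,
                    "mods": mods,
                    "charge": charge,
                    "sample": sample,
                    "rho": res.rho,
                    "corrected_m2": m2c,
                    "de_novo_percent": pct,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["peptide", "mods", "charge", "sample", "rho", "corrected_m2", "de_novo_percent"],
    )
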