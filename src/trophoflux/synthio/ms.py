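"""Synthetic Skyline-style histone peak tables with known label fractions.

Each peptidoform's MS1 isotopologue envelope follows the theoretical
natural isotope distribution of its elemental formula. In labelled
("treated") samples, every singly acetylated peptidoform's envelope is a
mixture: fraction ``1 - f`` of the natural envelope plus fraction ``f`` of
the same envelope shifted +2 Da (a 13C2-acetyl group from U-13C glucose).
``f`` is the recorded ground-truth de novo fraction.

A per-sample spike-in factor (lognormal, CV ``spikein_cv``) multiplies all
rows of a sample — heavy standards included — emulating injection-amount
variation; multiplicative lognormal noise with CV ``noise_cv`` is applied
per row. Coeluting isobaric pairs appear as one combined MS1 envelope
(stored under the first species) plus species-unique MS2 fragment rows
whose means are proportional to the true mixing shares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..chem import Peptidoform, natural_isotope_distribution, parse_mod_string, peptide_formula
from ..histone import PEAK_TABLE_COLUMNS
from .config import SimConfig

__all__ = ["gen_histone_peak_table"]

# heavy spike-in standards: heavy-arginine versions of two panel peptides
HEAVY_STANDARDS: tuple[tuple[str, int, str], ...] = (
    ("YRPGTVALR", 40, "heavy"),
    ("KSTGGKAPR", 8, "K9ac;heavy"),
)


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def _label_fraction(cfg, seq: str, mods: str) -> float:
    if np.isscalar(cfg.label_fractions):
        return float(cfg.label_fractions)
    return float(cfg.label_fractions.get((seq, mods), 0.0))


def gen_histone_peak_table(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a long peak table plus ground truth.

    Returns ``(table, truth)`` where ``truth`` holds per-peptidoform de
    novo fractions, per-sample spike-in factors, the isobaric mixing share
    and the clean (pre-noise) envelopes.
    """
    cfg = config.ms
    rng = config.rng("ms")
    samples = [f"ctrl_{i + 1}" for i in range(cfg.n_control)] + [
        f"treated_{i + 1}" for i in range(cfg.n_treated)
    ]
    labelled = {s: s.startswith("treated") for s in samples}
    spike = dict(zip(samples, _lognoise(rng, cfg.spikein_cv, len(samples))))

    # base abundances per form: fixed lognormal draw so forms differ
    forms = list(cfg.peptidoforms)
    base = cfg.base_area * rng.lognormal(0.0, 0.5, size=len(forms))

    pair_second = {b: a for a, b in cfg.isobaric_pairs}
    pair_first = {a: b for a, b in cfg.isobaric_pairs}

    envelopes: dict[tuple[str, str], np.ndarray] = {}
    rows: list[dict] = []
    truth_fracs: dict[tuple[str, str], float] = {}

    for (seq, offset, mods), amount in zip(forms, base):
        p = Peptidoform(seq, parse_mod_string(seq, mods, offset))
        env, _ = natural_isotope_distribution(peptide_formula(p), cfg.n_isotopologues)
        envelopes[(seq, mods)] = env
        if p.n_acetyl() == 1:
            truth_fracs[(seq, mods)] = _label_fraction(cfg, seq, mods)

    def ms1_rows(sample: str, seq: str, mods: str, amount: float) -> None:
        env = envelopes[(seq, mods)]
        f = truth_fracs.get((seq, mods), 0.0) if labelled[sample] else 0.0
        mixed = (1 - f) * env
        shifted = np.zeros_like(env)
        shifted[2:] = env[:-2]
        mixed = mixed + f * shifted
        areas = amount * spike[sample] * mixed * _lognoise(rng, cfg.noise_cv, len(mixed))
        for iso, area in enumerate(areas):
            rows.append(
                {
                    "sample": sample,
                    "peptide": seq,
                    "mods": mods,
                    "charge": 2,
                    "ms_level": 1,
                    "isotopologue": iso,
                    "fragment_id": "",
                    "area": float(area),
                    "heavy_flag": False,
                }
            )

    for sample in samples:
        for (seq, offset, mods), amount in zip(forms, base):
            if mods in pair_second:
                continue  # folded into its partner's combined MS1 peak
            if mods in pair_first:
                # combined isobaric MS1 peak: both species' material
                partner_idx = [i for i, (s2, _, m2) in enumerate(forms) if s2 == seq and m2 == pair_first[mods]]
                total = amount + (base[partner_idx[0]] if partner_idx else 0.0)
                pi = cfg.isobaric_mixing
                ms1_rows(sample, seq, mods, total)
                # species-unique MS2 fragments, means proportional to shares
                for species, share in ((mods, pi), (pair_first[mods], 1 - pi)):
                    for j in range(cfg.n_fragments):
                        noise = _lognoise(rng, cfg.noise_cv, 1)[0]
                        rows.append(
                            {
                                "sample": sample,
                                "peptide": seq,
                                "mods": species,
                                "charge": 2,
                                "ms_level": 2,
                                "isotopologue": 0,
                                "fragment_id": f"frag{j + 1}",
                                "area": float(0.1 * total * share * spike[sample] * noise),
                                "heavy_flag": False,
                            }
                        )
            else:
                ms1_rows(sample, seq, mods, amount)
        # heavy spike-in standards, constant amount across samples
        for seq, offset, mods in HEAVY_STANDARDS:
            noise = _lognoise(rng, cfg.noise_cv, 1)[0]
            rows.append(
                {
                    "sample": sample,
                    "peptide": seq,
                    "mods": mods,
                    "charge": 2,
                    "ms_level": 1,
                    "isotopologue": 0,
                    "fragment_id": "",
                    "area": float(cfg.base_area * spike[sample] * noise),
                    "heavy_flag": True,
                }
            )

    table = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    truth = {
        "label_fractions": truth_fracs,
        "spikein_factors": spike,
        "isobaric_mixing": cfg.isobaric_mixing,
        "envelopes": envelopes,
        "control_samples": [s for s in samples if not labelled[s]],
        "treated_samples": [s for s in samples if labelled[s]],
    }
    return table, truth
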