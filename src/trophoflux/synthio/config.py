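"""Simulation configuration with recorded ground truth.

One :class:`SimConfig` holds a master seed plus one block per data domain.
Identical configurations (seed included) produce byte-identical outputs;
each generator derives its own independent random stream from the master
seed so the domains do not perturb one another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MsConfig",
    "ScPopulation",
    "ScConfig",
    "ImageConfig",
    "MetabConfig",
    "ReferenceConfig",
    "SimConfig",
    "DEFAULT_PEPTIDOFORMS",
]

# Default peptidoform panel: N-terminal tryptic/Arg-C peptides of histone
# H3.1 and H4 with their common acetyl/methyl forms. Each entry is
# (peptide sequence, protein-residue offset, modification string).
# "K27me2;K36me1" and "K36me3" on the H3 27-40 backbone are the canonical
# coeluting isobaric pair. The H3 41-49 unmodified peptide serves as the
# total-H3 indicator.
DEFAULT_PEPTIDOFORMS: tuple[tuple[str, int, str], ...] = (
    ("KSTGGKAPR", 8, "unmod"),       # H3 9-17
    ("KSTGGKAPR", 8, "K9ac"),
    ("KSTGGKAPR", 8, "K14ac"),
    ("KQLATKAAR", 17, "unmod"),      # H3 18-26
    ("KQLATKAAR", 17, "K18ac"),
    ("KQLATKAAR", 17, "K23ac"),
    ("KSAPATGGVKKPHR", 26, "unmod"),  # H3 27-40
    ("KSAPATGGVKKPHR", 26, "K27ac"),
    ("KSAPATGGVKKPHR", 26, "K36me3"),
    ("KSAPATGGVKKPHR", 26, "K27me2;K36me1"),
    ("YRPGTVALR", 40, "unmod"),      # H3 41-49, total-H3 indicator
    ("GKGGKGLGKGGAKR", 3, "unmod"),  # H4 4-17
    ("GKGGKGLGKGGAKR", 3, "K12ac"),
    ("GKGGKGLGKGGAKR", 3, "K16ac"),
)


@dataclass
class MsConfig:
    """Histone MS1/MS2 peak-table simulation.

    ``label_fractions`` gives the true de novo (13C2-acetyl) fraction f per
    singly acetylated peptidoform, keyed by (sequence, mods); a plain float
    applies to all of them. ``isobaric_mixing`` is the true share of the
    first species of each isobaric pair in the combined MS1 peak.
    """

    peptidoforms: tuple[tuple[str, int, str], ...] = DEFAULT_PEPTIDOFORMS
    n_control: int = 3
    n_treated: int = 3
    label_fractions: float | Mapping[tuple[str, str], float] = 0.2
    spikein_cv: float = 0.2
    noise_cv: float = 0.05
    n_isotopologues: int = 4
    isobaric_pairs: tuple[tuple[str, str], ...] = (("K36me3", "K27me2;K36me1"),)
    isobaric_mixing: float = 0.6
    n_fragments: int = 3
    base_area: float = 1e6

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.spikein_cv < 0:
            raise ValueError("CVs must be non-negative")
        fracs = (
            [self.label_fractions]
            if np.isscalar(self.label_fractions)
            else list(self.label_fractions.values())
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("label fractions must lie in [0, 1]")
        if not 0 <= self.isobaric_mixing <= 1:
            raise ValueError("isobaric mixing proportion must lie in [0, 1]")


@dataclass
class ScPopulation:
    """A simulated cell population hashed with one HTO tag.

    ``shifts`` maps signature names to the log-mean shift delta applied to
    that signature's genes in this population (1.0 = one natural-log unit).
    """

    name: str
    n_cells: int
    tag: str
    shifts: Mapping[str, float] = field(default_factory=dict)


@dataclass
class ScConfig:
    """Droplet scRNA-seq + cell-hashing simulation.

    RNA counts are negative binomial (gamma-Poisson) with lognormal
    gene-level means and fixed dispersion; a designated block of "MT-"
    genes receives a per-cell Beta-distributed share of counts. HTO counts
    are Poisson ambient background on every tag with a multiplier on the
    cell's own tag(s); doublets sum two cells and carry two dominant tags.
    """

    populations: tuple[ScPopulation, ...] = (
        ScPopulation("polar", 500, "A0251", {"pTE": 1.0}),
        ScPopulation("mural", 500, "A0252", {"mTE": 1.0}),
    )
    n_genes: int = 1500
    doublet_rate: float = 0.05
    ambient_hto_mean: float = 5.0
    dominant_multiplier: float = 50.0
    dispersion: float = 0.1
    mean_depth: float = 12000.0
    depth_cv: float = 0.3
    n_mito_genes: int = 10
    mito_beta: tuple[float, float] = (2.0, 20.0)
    extra_signatures: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("need at least one population")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must lie in [0, 1)")


@dataclass
class ImageConfig:
    """Circular aggregate scenes: outer nucleus ring, inner nuclei, and a
    polarity channel worth ``apical_enrichment x base`` in the apical rim
    (between the outer nuclei and the aggregate contour) and ``base``
    elsewhere inside the aggregate."""

    n_aggregates: int = 1
    size: int = 192
    aggregate_radius: float = 70.0
    rim_width: float = 5.0
    nucleus_radius: float = 7.0
    n_outer: int = 18
    n_inner: int = 5
    apical_enrichment: float = 3.0
    base_intensity: float = 100.0
    noise_sd: float = 0.0
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.apical_enrichment < 0:
            raise ValueError("apical_enrichment must be >= 0")
        if self.rim_width >= self.nucleus_radius * 2:
            raise ValueError("rim must be thinner than a nucleus diameter")


@dataclass
class MetabConfig:
    """Targeted-metabolomics peak tables with internal standards, a
    dilution series and per-sample protein content.

    ``fold_changes`` is the true treated/control concentration ratio, per
    analyte (scalar applies to all). ``protein_confound`` scales both the
    treated samples' material amount and their protein content, creating a
    spurious group effect that protein normalization must remove."""

    n_analytes: int = 20
    n_per_group: int = 3
    groups: tuple[str, str] = ("0mM", "4mM")
    fold_changes: float | Sequence[float] = 1.0
    noise_cv: float = 0.1
    sample_factor_cv: float = 0.2
    dilution_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    base_concentration: float = 4.0
    protein_mean_ug: float = 100.0
    protein_cv: float = 0.1
    protein_confound: float = 1.0

    def __post_init__(self) -> None:
        if len(self.dilution_levels) < 3:
            raise ValueError("dilution series needs at least 3 levels")
        if self.base_concentration <= 0:
            raise ValueError("concentrations must be positive")
        fcs = [self.fold_changes] if np.isscalar(self.fold_changes) else list(self.fold_changes)
        if any(fc <= 0 for fc in fcs):
            raise ValueError("fold changes must be positive")


@dataclass
class ReferenceConfig:
    """2D reference embedding with Gaussian clusters per developmental stage,
    query points, and neighborhood membership lists."""

    stages: tuple[str, ...] = ("E5", "E6", "E7")
    n_per_stage: int = 50
    cluster_sd: float = 1.0
    centroid_spacing: float = 10.0
    n_queries: int = 30
    neighborhoods_per_cell: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("need at least one stage label")


@dataclass
class SimConfig:
    """Master simulation configuration: a seed plus per-domain blocks."""

    seed: int = 0
    ms: MsConfig = field(default_factory=MsConfig)
    sc: ScConfig = field(default_factory=ScConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    metab: MetabConfig = field(default_factory=MetabConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)

    def rng(self, domain: str) -> np.random.Generator:
        """Independent, reproducible stream per domain."""
        tag = zlib.crc32(domain.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "SimConfig":
        blocks = {}
        for name, block_cls in (
            ("ms", MsConfig),
            ("sc", ScConfig),
            ("image", ImageConfig),
            ("metab", MetabConfig),
            ("reference", ReferenceConfig),
        ):
            sub = dict(raw.get(name, {}))
            if name == "sc" and "populations" in sub:
                sub["populations"] = tuple(
                    ScPopulation(**p) if isinstance(p, Mapping) else p
                    for p in sub["populations"]
                )
            known = block_cls.__dataclass_fields__
            unknown = set(sub) - set(known)
            if unknown:
                raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
            blocks[name] = block_cls(**sub)
        return cls(seed=int(raw.get("seed", 0)), **blocks)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
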