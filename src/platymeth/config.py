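"""Simulation configuration: study design, noise model parameters, injected effects.

The default design mirrors the experiment the pipeline targets: one control
sample (CT 12 h) plus three methyl-jasmonate time points (MJ 12/24/48 h) for
the methylome, and eight tissues plus the same four treatment samples for
expression.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Methylome / treatment samples: control then the three MJ time points.
METH_SAMPLES = ("CT_12h", "MJ_12h", "MJ_24h", "MJ_48h")

#: Treatment sample -> time point label used in DMC outputs.
TIMEPOINT_OF_SAMPLE = {"MJ_12h": "12h", "MJ_24h": "24h", "MJ_48h": "48h"}

#: The eight tissues profiled by RNA-seq.
TISSUES = ("root", "leaf", "stem", "seed", "petal", "pistil", "sepal", "stamen")

EFFECT_REGIONS = ("upstream", "body", "both")


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class FamilyEffect:
    """A methylation shift injected into every gene of one family.

    ``delta_pp`` is in percentage points (e.g. -20 lowers the true methylation
    proportion by 0.20, clipped to [0, 1]); ``region`` selects the gene span
    affected ('upstream', 'body' or 'both').
    """

    family: str
    sample: str
    delta_pp: float
    region: str = "both"

    def __post_init__(self) -> None:
        if self.region not in EFFECT_REGIONS:
            raise ConfigError(f"unknown effect region {self.region!r}")


@dataclass(frozen=True)
class ExpressionEffect:
    """A log2 expression shift for every gene of one family in one sample/tissue."""

    family: str
    sample: str
    log2_effect: float


@dataclass
class SimulationConfig:
    """All knobs of the synthetic genome/methylome/transcriptome generator.

    ``seed`` is mandatory: every random draw flows from it, so identical
    configurations reproduce byte-identical outputs.
    """

    seed: int
    n_chromosomes: int = 1
    chrom_length_bp: int = 1_000_000
    gc_fraction: float = 0.36
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1000, 3000)
    family_spec: dict[str, int] = field(
        default_factory=lambda: {"CYP716": 35, "bAS": 24, "GGPS": 32}
    )
    context_means: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.891, "CHG": 0.724, "CHH": 0.189}
    )
    site_dispersion: float = 50.0  # beta concentration; math.inf = no site variation
    coverage_mean: float = 15.0
    coverage_dispersion: float = 10.0  # negative-binomial size
    non_conversion_rate: float = 0.005
    family_effects: list[FamilyEffect] = field(default_factory=list)
    expression_effects: list[ExpressionEffect] = field(default_factory=list)
    coupling: float = 0.0  # expression log2 shift per -10 pp methylation shift, signed
    samples: tuple[str, ...] = METH_SAMPLES
    tissues: tuple[str, ...] = TISSUES
    expression_baseline_median: float = 200.0
    expression_log_sd: float = 0.8  # natural-log sd of per-gene baseline means
    expression_nb_size: float = 100.0  # negative-binomial size of fragment counts
    flank_bp: int = 2000
    min_intergenic_gap_bp: int = 1  # 2 * flank_bp keeps regulatory spans disjoint

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ConfigError("chromosome count and length must be positive")
        for name, value in (("gc_fraction", self.gc_fraction), ("non_conversion_rate", self.non_conversion_rate)):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for ctx, mu in self.context_means.items():
            if ctx not in ("CG", "CHG", "CHH"):
                raise ConfigError(f"unknown context {ctx!r} in context_means")
            if not 0.0 <= mu <= 1.0:
                raise ConfigError(f"context mean for {ctx} must be in [0, 1]")
        if set(self.context_means) != {"CG", "CHG", "CHH"}:
            raise ConfigError("context_means must cover CG, CHG and CHH")
        if not self.site_dispersion > 0:
            raise ConfigError("site_dispersion must be > 0")
        if not self.coverage_mean > 0:
            raise ConfigError("coverage_mean must be > 0")
        if not self.coverage_dispersion > 0:
            raise ConfigError("coverage_dispersion must be > 0")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if sum(self.family_spec.values()) > self.n_genes:
            raise ConfigError("family_spec gene counts exceed n_genes")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError("gene_length_range must satisfy 0 < min <= max")
        if self.min_intergenic_gap_bp < 1:
            raise ConfigError("min_intergenic_gap_bp must be >= 1")
        mean_span = (lo + hi) / 2 + 2 * self.flank_bp
        if self.chrom_length_bp < 10 * mean_span and self.n_genes > 0:
            raise ConfigError(
                f"chromosomes of {self.chrom_length_bp} bp are too short for gene spans of ~{mean_span:.0f} bp"
            )
        known_families = set(self.family_spec)
        for eff in self.family_effects:
            if eff.family not in known_families:
                raise ConfigError(f"family effect names unknown family {eff.family!r}")
            if eff.sample not in self.samples:
                raise ConfigError(f"family effect names unknown sample {eff.sample!r}")
        valid_expr_samples = set(self.samples) | set(self.tissues)
        for eff in self.expression_effects:
            if eff.family not in known_families:
                raise ConfigError(f"expression effect names unknown family {eff.family!r}")
            if eff.sample not in valid_expr_samples:
                raise ConfigError(f"expression effect names unknown sample/tissue {eff.sample!r}")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["samples"] = list(self.samples)
        d["tissues"] = list(self.tissues)
        if math.isinf(self.site_dispersion):
            d["site_dispersion"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "family_effects" in d:
            d["family_effects"] = [
                fe if isinstance(fe, FamilyEffect) else FamilyEffect(**fe) for fe in d["family_effects"]
            ]
        if "expression_effects" in d:
            d["expression_effects"] = [
                ee if isinstance(ee, ExpressionEffect) else ExpressionEffect(**ee)
                for ee in d["expression_effects"]
            ]
        for key in ("gene_length_range", "samples", "tissues"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("site_dispersion") == "inf":
            d["site_dispersion"] = math.inf
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def mj_hypomethylation_scenario(seed: int, **overrides) -> SimulationConfig:
    """The packaged default scenario: CYP716/bAS hypomethylation with coupling.

    CYP716 genes lose 20 pp of CG-context methylation over upstream + body at
    all three MJ time points; bAS genes lose the same only at 48 h.  A
    negative coupling of -0.5 converts each -10 pp methylation shift into a
    +0.5 log2 expression shift for the same genes, emulating de-repression.
    """
    defaults = dict(
        seed=seed,
        n_chromosomes=1,
        chrom_length_bp=4_500_000,
        n_genes=600,
        min_intergenic_gap_bp=4000,  # 2 * flank: no gene sits in another's regulatory span
        family_spec={"CYP716": 35, "bAS": 24, "GGPS": 32, "CYP76": 30, "CYP72": 28, "CYP71": 26},
        family_effects=[
            FamilyEffect("CYP716", "MJ_12h", -20.0, "both"),
            FamilyEffect("CYP716", "MJ_24h", -20.0, "both"),
            FamilyEffect("CYP716", "MJ_48h", -20.0, "both"),
            FamilyEffect("bAS", "MJ_48h", -20.0, "both"),
        ],
        expression_effects=[ExpressionEffect("CYP716", "root", 3.0), ExpressionEffect("bAS", "root", 2.0)],
        coupling=-0.5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
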