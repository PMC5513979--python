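"""Configuration objects for the analysis pipeline and the simulator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .types import STRESS_TREATMENTS


class ConfigError(ValueError):
    """Raised when a configuration value is out of range."""


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the full analysis.

    The defaults reproduce the standard calling rule for single-library
    designs: a unit is differentially abundant when the posterior
    probability that |log2 fold change| >= ``fc_threshold_log2`` exceeds
    ``postp_threshold`` and the posterior-mean |log2 fold change| also
    meets the threshold.
    """

    fc_threshold_log2: float = 1.0
    postp_threshold: float = 0.95
    alpha: float = 0.05
    min_species_conserved: int = 2
    min_gene_set_size: int = 5
    seed: int = 0
    # posterior integration grid for the DE engine
    grid_lo: float = -10.0
    grid_hi: float = 10.0
    grid_step: float = 0.01
    # whether the fold-change clause of the calling rule uses the
    # posterior-mean log2FC ("posterior") or the raw count ratio ("raw")
    fc_clause: str = "posterior"
    # conservation screen: None means all non-dinoflagellate species
    focal_species: tuple[str, ...] | None = None
    # gene sets for enrichment: annotation column holding the grouping
    gene_set_column: str = "kegg_module"
    # KS exact p: full enumeration when C(n+m, n) <= enum_limit, else
    # Monte-Carlo with n_permutations relabelings
    enum_limit: int = 20_000
    n_permutations: int = 10_000
    # fingerprint/ordination
    scale_columns: bool = True
    n_components: int = 5
    # prior fitting is done on at most this many (seeded) subsampled units
    max_prior_fit_units: int = 5_000

    def validate(self) -> "PipelineConfig":
        if self.fc_threshold_log2 <= 0:
            raise ConfigError("fc_threshold_log2 must be positive")
        if not 0.0 < self.postp_threshold < 1.0:
            raise ConfigError("postp_threshold must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_species_conserved < 2:
            raise ConfigError("min_species_conserved must be >= 2")
        if self.min_gene_set_size < 1:
            raise ConfigError("min_gene_set_size must be >= 1")
        if self.grid_lo >= self.grid_hi or self.grid_step <= 0:
            raise ConfigError("invalid posterior grid bounds/step")
        if self.fc_clause not in ("posterior", "raw"):
            raise ConfigError("fc_clause must be 'posterior' or 'raw'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "focal_species" in raw and raw["focal_species"] is not None:
            raw["focal_species"] = tuple(raw["focal_species"])
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["focal_species"] is not None:
            data["focal_species"] = list(data["focal_species"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class PlantedConservedSpec:
    """A block of orthologs planted with a concordant cross-species response.

    ``n`` orthologs spanning every species in ``species`` receive the same
    signed effect (|log2FC| = ``magnitude``) in the listed treatments.
    ``direction`` is ``"up"``, ``"down"`` or ``"random"`` (sign drawn per
    ortholog, biased toward decreases as is typical of stress responses).
    """

    n: int
    species: tuple[str, ...]
    treatments: tuple[str, ...]
    direction: str = "random"
    magnitude: float = 2.0
    #: optional replete-condition ortholog mean; when set, member contigs
    #: split it evenly instead of drawing from the baseline distribution
    baseline: float | None = None

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("planted block size must be >= 0")
        if len(self.species) < 2:
            raise ConfigError("planted conserved species subsets need >= 2 species")
        bad = set(self.treatments) - set(STRESS_TREATMENTS)
        if bad or not self.treatments:
            raise ConfigError(f"planted treatments must be within {STRESS_TREATMENTS}")
        if self.direction not in ("up", "down", "random"):
            raise ConfigError("direction must be up/down/random")
        if self.magnitude <= 0:
            raise ConfigError("magnitude must be positive")
        if self.baseline is not None and self.baseline <= 0:
            raise ConfigError("baseline must be positive")


def _default_species() -> tuple[str, ...]:
    return ("dia1", "hap1", "hap2", "din1", "din2")


def _default_planted() -> tuple[PlantedConservedSpec, ...]:
    focal = ("dia1", "hap1", "hap2")
    return (
        PlantedConservedSpec(40, focal, ("lowP",), "random"),
        PlantedConservedSpec(25, focal, ("lowN",), "random"),
        PlantedConservedSpec(10, focal, ("lowN", "lowP"), "down"),
    )


@dataclass
class SimulationConfig:
    """Shape and statistical structure of a synthetic experiment.

    Defaults emulate a five-species design: one diatom-like and two
    haptophyte-like species that remodel ~10% of their transcriptome
    under nutrient stress, and two dinoflagellate-like species with
    strongly suppressed transcriptional responses (~0.2%).  Contigs are
    generated inside orthologs partitioned into core (all species),
    shared (a proper subset of >= 2) and unique (one species) groups.
    """

    species: tuple[str, ...] = field(default_factory=_default_species)
    dino_species: tuple[str, ...] = ("din1", "din2")
    n_core: int = 1000
    n_shared: int = 1500
    n_unique_per_species: int = 300
    contigs_per_ortholog: tuple[int, int] = (1, 3)
    # contig length ~ LogNormal(meanlog, sdlog), floored at 150 bp
    length_meanlog: float = 6.9
    length_sdlog: float = 0.6
    # replete-condition mean expression ~ LogNormal(meanlog, sdlog)
    baseline_meanlog: float = 3.4
    baseline_sdlog: float = 1.3
    de_fraction: float = 0.10
    dino_de_fraction: float = 0.002
    effect_size_range: tuple[float, float] = (1.0, 3.0)
    conserved_planted: tuple[PlantedConservedSpec, ...] = field(
        default_factory=_default_planted
    )
    kegg_annotated_fraction: float = 0.2
    n_kegg_modules: int = 30
    noise: str = "poisson"
    nb_dispersion: float = 0.1
    # optional per-treatment sequencing-depth multipliers; the study does
    # not report per-library depths, so these default to equal depths
    depth_multiplier: dict[str, float] = field(
        default_factory=lambda: {"replete": 1.0, "lowN": 1.0, "lowP": 1.0}
    )
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if len(self.species) < 1:
            raise ConfigError("need at least one species")
        if len(set(self.species)) != len(self.species):
            raise ConfigError("duplicate species ids")
        if not set(self.dino_species) <= set(self.species):
            raise ConfigError("dino_species must be a subset of species")
        for name in ("de_fraction", "dino_de_fraction", "kegg_annotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.contigs_per_ortholog
        if lo < 1 or hi < lo:
            raise ConfigError("invalid contigs_per_ortholog range")
        lo, hi = self.effect_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("invalid effect_size_range")
        if self.noise not in ("poisson", "nb"):
            raise ConfigError("noise must be 'poisson' or 'nb'")
        if self.noise == "nb" and self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for spec in self.conserved_planted:
            spec.validate()
            if not set(spec.species) <= set(self.species):
                raise ConfigError(
                    f"planted species {spec.species} not all in species list"
                )
        return self

    def de_fraction_for(self, species_id: str) -> float:
        if species_id in self.dino_species:
            return self.dino_de_fraction
        return self.de_fraction

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("species", "dino_species"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("contigs_per_ortholog", "effect_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "conserved_planted" in raw:
            raw["conserved_planted"] = tuple(
                PlantedConservedSpec(
                    n=int(d["n"]),
                    species=tuple(d["species"]),
                    treatments=tuple(d["treatments"]),
                    direction=d.get("direction", "random"),
                    magnitude=float(d.get("magnitude", 2.0)),
                    baseline=(
                        float(d["baseline"]) if d.get("baseline") is not None else None
                    ),
                )
                for d in raw["conserved_planted"]
            )
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["species"] = list(data["species"])
        data["dino_species"] = list(data["dino_species"])
        data["contigs_per_ortholog"] = list(data["contigs_per_ortholog"])
        data["effect_size_range"] = list(data["effect_size_range"])
        data["conserved_planted"] = [
            {
                "n": s["n"],
                "species": list(s["species"]),
                "treatments": list(s["treatments"]),
                "direction": s["direction"],
                "magnitude": s["magnitude"],
                "baseline": s["baseline"],
            }
            for s in data["conserved_planted"]
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def focal_species_for(
    config: PipelineConfig, species: Sequence[str], dino: Sequence[str]
) -> tuple[str, ...]:
    """Focal subset for the conservation screen.

    Defaults to every non-dinoflagellate species, mirroring the practice
    of excluding taxa with post-transcriptional regulation from
    cross-species response screens.
    """
    if config.focal_species is not None:
        missing = set(config.focal_species) - set(species)
        if missing:
            raise ConfigError(f"focal species not in inputs: {sorted(missing)}")
        return tuple(config.focal_species)
    return tuple(s for s in species if s not in set(dino))
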