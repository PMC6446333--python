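"""Synthetic 55K-style genotype simulator with ground-truth labels.

The generative model mirrors what a wheat SNP array sees when a pair of
wheat chromosomes has been replaced by an alien homoeologous pair:

* every marker sits at a known reference position (uniform along the
  genome, density proportional to chromosome length);
* in euploid wheat backgrounds a marker fails to call with a small
  background probability (a few designated chromosomes carry an elevated
  rate, emulating parent/reference divergence);
* a per-marker *cross-hybridization* flag says whether the probe also
  detects a site anywhere in the alien donor genome — the donor yields a
  call exactly at those markers;
* a per-marker *retained* flag (a subset of the cross-hybridizing markers)
  says whether the probe detects a site on the alien homoeolog itself, so
  in a substitution line a marker on the substituted chromosome still
  calls iff it is retained and the call does not drop out at the
  background rate.  The retained/cross-hybridizing flags are drawn once
  per marker and shared by the donor and every substitution line: all of
  them interrogate the same physical alien sequence, which is what makes
  the shared-homozygous-allele filter meaningful.

Calls read from the alien chromosome are homozygous (the donor is inbred);
the alien allele matches the wheat parents' allele with a configurable
probability, independently per marker.

Defaults encode the rates the screen is designed around: 57.7% of markers
cross-hybridizing with the donor, ~1.2% background missingness, ~8% on
designated divergent chromosomes, and conditional retention 0.693 so that
~40% of the substituted chromosome's markers still call in a substitution
line (hence ~60% missing there).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ConsistencyError
from .genotypes import GenotypeMatrix, MarkerMap

ROLES = (
    "wheat_parent",
    "alien_donor",
    "substitution_line",
    "addition_line",
    "no_alien_derivative",
)

#: approximate bread-wheat reference chromosome lengths (bp)
WHEAT_CHROMOSOME_LENGTHS: dict[str, int] = {
    "1A": 594_102_056, "1B": 689_851_870, "1D": 495_453_186,
    "2A": 780_798_557, "2B": 801_256_715, "2D": 651_852_609,
    "3A": 750_843_639, "3B": 830_829_764, "3D": 615_552_423,
    "4A": 744_588_157, "4B": 673_617_499, "4D": 509_857_067,
    "5A": 709_773_743, "5B": 713_149_757, "5D": 566_080_677,
    "6A": 618_079_260, "6B": 720_988_478, "6D": 473_592_718,
    "7A": 736_706_236, "7B": 750_620_385, "7D": 638_686_055,
}


@dataclass(frozen=True)
class SampleSpec:
    """One simulated sample: a name, a role, and (for substitution lines)
    which wheat chromosome the alien homoeolog replaces."""

    name: str
    role: str
    substituted_chromosome: str | None = None


@dataclass
class SimulationConfig:
    chromosome_lengths: dict[str, int]
    n_markers: int
    samples: tuple[SampleSpec, ...]
    p_cross_hybridize: float = 0.577
    p_background_missing: float = 0.012
    divergent_chromosomes: dict[str, float] = field(default_factory=dict)
    p_retained_on_substituted: float = 0.693
    p_heterozygous: float = 0.01
    p_alien_allele_matches_wheat: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.chromosome_lengths:
            raise ConfigurationError("chromosome_lengths: at least one chromosome required")
        for chrom, length in self.chromosome_lengths.items():
            if int(length) <= 0:
                raise ConfigurationError(f"chromosome_lengths[{chrom!r}]: length must be > 0")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers: must be >= 1")
        for name in (
            "p_cross_hybridize",
            "p_background_missing",
            "p_retained_on_substituted",
            "p_heterozygous",
            "p_alien_allele_matches_wheat",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: probability {v} outside [0, 1]")
        for chrom, rate in self.divergent_chromosomes.items():
            if chrom not in self.chromosome_lengths:
                raise ConfigurationError(
                    f"divergent_chromosomes: unknown chromosome {chrom!r}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"divergent_chromosomes[{chrom!r}]: rate {rate} outside [0, 1]"
                )
        if not self.samples:
            raise ConfigurationError("samples: at least one sample required")
        self.samples = tuple(self.samples)
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ConfigurationError("samples: duplicate sample names")
        for s in self.samples:
            if s.role not in ROLES:
                raise ConfigurationError(f"samples[{s.name!r}].role: unknown role {s.role!r}")
            if s.role == "substitution_line":
                if s.substituted_chromosome is None:
                    raise ConfigurationError(
                        f"samples[{s.name!r}].substituted_chromosome: required for a substitution line"
                    )
                if s.substituted_chromosome not in self.chromosome_lengths:
                    raise ConfigurationError(
                        f"samples[{s.name!r}].substituted_chromosome: "
                        f"{s.substituted_chromosome!r} not among the configured chromosomes"
                    )

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    def missing_rate(self, chrom: str) -> float:
        """Background no-call rate for a wheat-derived chromosome."""
        return self.divergent_chromosomes.get(chrom, self.p_background_missing)

    # -- (de)serialization -----------------------------------------------
    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        samples = tuple(
            SampleSpec(
                name=s["name"],
                role=s["role"],
                substituted_chromosome=s.get("substituted_chromosome"),
            )
            for s in data.pop("samples")
        )
        lengths = {str(k): int(v) for k, v in dict(data.pop("chromosome_lengths")).items()}
        return cls(chromosome_lengths=lengths, samples=samples, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["samples"] = [asdict(s) for s in self.samples]
        return d


def default_study_config(seed: int = 0, n_markers: int = 51_159) -> SimulationConfig:
    """The study-design cohort: two wheat parents, the alien donor, and
    three independent substitution lines sharing one substituted
    chromosome (4B), over 21 wheat chromosomes with 2D and 7B carrying
    elevated parent-divergence missingness."""
    return SimulationConfig(
        chromosome_lengths=dict(WHEAT_CHROMOSOME_LENGTHS),
        n_markers=n_markers,
        samples=(
            SampleSpec("YY2", "wheat_parent"),
            SampleSpec("CM41", "wheat_parent"),
            SampleSpec("AS6", "alien_donor"),
            SampleSpec("SubL1", "substitution_line", "4B"),
            SampleSpec("SubL2", "substitution_line", "4B"),
            SampleSpec("SubL3", "substitution_line", "4B"),
        ),
        divergent_chromosomes={"2D": 0.079, "7B": 0.083},
        seed=seed,
    )


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests.

    ``markers``: one row per marker (marker, chrom, pos, cross_hybridizing,
    retained, wheat_allele, alien_allele); ``samples``: one record per
    sample (name, role, substituted_chromosome).
    """

    markers: pd.DataFrame
    samples: list[dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": self.samples,
            "markers": self.markers.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        markers = pd.DataFrame(payload["markers"])
        canonical = [
            "marker", "chrom", "pos", "cross_hybridizing", "retained",
            "wheat_allele", "alien_allele",
        ]
        if set(canonical) == set(markers.columns):
            markers = markers[canonical]
        return cls(markers=markers, samples=payload["samples"])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def simulate_marker_map(config: SimulationConfig, seed: int | None = None) -> MarkerMap:
    """Place ``n_markers`` markers uniformly along the configured genome.

    Each marker lands on a chromosome with probability proportional to its
    length and uniformly within it; ids are assigned in genome order.
    Deterministic given (config, seed).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 0)
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = offsets[-1]
    global_pos = rng.integers(0, total, size=config.n_markers)
    idx = np.searchsorted(offsets, global_pos, side="right") - 1
    pos = global_pos - offsets[idx] + 1  # 1-based within chromosome
    frame = pd.DataFrame({"chrom": np.array(chroms, dtype=object)[idx], "pos": pos})
    order = np.lexsort((frame["pos"].to_numpy(), idx))
    frame = frame.iloc[order].reset_index(drop=True)
    width = max(6, len(str(config.n_markers)))
    frame.insert(0, "marker", [f"M{i + 1:0{width}d}" for i in range(len(frame))])
    return MarkerMap(frame)


def simulate_genotypes(
    marker_map: MarkerMap,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw a genotype matrix for the configured cohort over *marker_map*.

    Wheat parents, addition lines and alien-free derivatives all behave as
    euploid wheat (an added alien pair leaves every wheat target in place,
    so chip missingness cannot see it).  Deterministic given (config, seed).
    """
    seed = config.seed if seed is None else seed
    extra = set(marker_map.frame["chrom"]) - set(config.chromosome_lengths)
    if extra:
        raise ConsistencyError(
            f"marker map names chromosome(s) {sorted(extra)} absent from the config"
        )
    rng = _rng(seed, 1)
    mf = marker_map.frame
    n = len(mf)
    chrom = mf["chrom"].to_numpy()

    # per-marker properties, shared across every sample
    wheat_allele = np.where(rng.random(n) < 0.5, "AA", "BB").astype(object)
    cross_hyb = rng.random(n) < config.p_cross_hybridize
    retained = cross_hyb & (rng.random(n) < config.p_retained_on_substituted)
    alien_match = rng.random(n) < config.p_alien_allele_matches_wheat
    other = np.where(wheat_allele == "AA", "BB", "AA").astype(object)
    alien_allele = np.where(alien_match, wheat_allele, other).astype(object)

    p_miss = np.full(n, config.p_background_missing)
    for c, rate in config.divergent_chromosomes.items():
        p_miss[chrom == c] = rate

    columns: dict[str, np.ndarray] = {}
    for spec in config.samples:
        u_miss = rng.random(n)
        u_het = rng.random(n)
        if spec.role == "alien_donor":
            calls = np.where(cross_hyb, alien_allele, "NC").astype(object)
        else:
            calls = wheat_allele.copy()
            calls[u_het < config.p_heterozygous] = "AB"
            calls[u_miss < p_miss] = "NC"
            if spec.role == "substitution_line":
                on = chrom == spec.substituted_chromosome
                # wheat target gone: a call survives only through the alien
                # homoeolog, at the plain background drop-out rate
                alien_calls = np.where(
                    retained & (u_miss >= config.p_background_missing),
                    alien_allele,
                    "NC",
                ).astype(object)
                calls[on] = alien_calls[on]
        columns[spec.name] = calls

    calls_frame = pd.DataFrame(columns, index=pd.Index(mf["marker"], name="marker"))
    truth = SimulationTruth(
        markers=pd.DataFrame(
            {
                "marker": mf["marker"].to_numpy(),
                "chrom": chrom,
                "pos": mf["pos"].to_numpy(),
                "cross_hybridizing": cross_hyb,
                "retained": retained,
                "wheat_allele": wheat_allele,
                "alien_allele": alien_allele,
            }
        ),
        samples=[asdict(s) for s in config.samples],
    )
    return GenotypeMatrix(calls_frame), truth


def expected_missing_rate(config: SimulationConfig, role: str, chrom: str,
                          substituted: bool = False) -> float:
    """Closed-form per-marker no-call probability under the model.

    Used by convergence tests; mirrors the generative draws exactly.
    """
    if role == "alien_donor":
        return 1.0 - config.p_cross_hybridize
    if role == "substitution_line" and substituted:
        return 1.0 - (
            config.p_cross_hybridize
            * config.p_retained_on_substituted
            * (1.0 - config.p_background_missing)
        )
    return config.missing_rate(chrom)
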