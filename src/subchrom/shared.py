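"""Shared homozygous-allele filter for cross-hybridizing markers.

Markers on the substituted chromosome that still call in every
substitution line *and* in the alien donor, homozygous and with the
identical allele throughout, are the markers whose probes read both the
wheat chromosome and its alien homoeolog.  Heterozygous calls are
excluded outright: on relatives of the design species, ambiguous
hybridization signals surface as spurious AB calls, so only clean
homozygous concordance is trusted.

Exclusion reasons are assigned with fixed precedence
``missing_in_some > heterozygous_in_some > allele_discordant`` so the
reason tally is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix, MarkerMap, check_map_in_genotypes
from .windows import WindowSpec

EXCLUSION_REASONS = ("missing_in_some", "heterozygous_in_some", "allele_discordant")


@dataclass
class SharedMarkerSet:
    """Markers concordantly homozygous across the queried samples.

    ``frame`` columns: marker, pos, allele (AA or BB), sorted by position.
    ``excluded`` tallies the markers removed, by reason; included plus
    excluded always equals ``n_tested``.
    """

    chromosome: str
    frame: pd.DataFrame
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return len(self.frame)

    @property
    def n_tested(self) -> int:
        return self.n_included + sum(self.excluded.values())


def filter_shared_homozygous(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    chromosome: str,
    lines: Sequence[str],
    alien: str,
) -> SharedMarkerSet:
    """Intersect homozygous calls across substitution lines and the donor.

    A mapped marker on *chromosome* is included iff its call is AA or BB
    in every line and in the alien donor, and all those calls are the
    same allele.
    """
    if not lines:
        raise InputError("at least one substitution line required")
    if alien in set(lines):
        raise InputError(f"alien sample {alien!r} also listed among the lines")
    queried = list(lines) + [alien]
    calls = np.column_stack(
        [genotypes.sample_calls(s).to_numpy(dtype=object) for s in queried]
    )
    placed, _ = check_map_in_genotypes(marker_map, genotypes)
    on_chrom = marker_map.markers_on(chromosome)
    on_chrom = on_chrom[on_chrom["marker"].isin(set(placed["marker"]))]
    idx = genotypes.markers.get_indexer(on_chrom["marker"])
    sub = calls[idx]  # markers-on-chromosome x queried-samples

    any_missing = (sub == "NC").any(axis=1)
    any_het = (sub == "AB").any(axis=1)
    concordant = (sub == sub[:, [0]]).all(axis=1)
    included = ~any_missing & ~any_het & concordant
    reason = np.where(
        any_missing,
        "missing_in_some",
        np.where(any_het, "heterozygous_in_some", "allele_discordant"),
    )
    excluded = {
        r: int(((reason == r) & ~included).sum()) for r in EXCLUSION_REASONS
    }
    frame = pd.DataFrame(
        {
            "marker": on_chrom["marker"].to_numpy()[included],
            "pos": on_chrom["pos"].to_numpy()[included],
            "allele": sub[included, 0],
        }
    ).sort_values(["pos", "marker"], kind="mergesort").reset_index(drop=True)
    return SharedMarkerSet(chromosome=chromosome, frame=frame, excluded=excluded)


def coverage_report(
    shared: SharedMarkerSet,
    chromosome_length: int,
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Shared-marker counts in a non-overlapping window partition.

    Columns: start, end (0-based half-open), n_shared, empty (True where
    no shared marker falls in the window) — the quick check that the
    shared set spans the whole chromosome.
    """
    if chromosome_length <= 0:
        raise InputError("chromosome_length must be > 0")
    starts = np.arange(0, chromosome_length, spec.window_size, dtype=np.int64)
    ends = starts + spec.window_size
    positions = np.sort(shared.frame["pos"].to_numpy())
    counts = np.searchsorted(positions, ends, side="right") - np.searchsorted(
        positions, starts, side="right"
    )
    return pd.DataFrame(
        {"start": starts, "end": ends, "n_shared": counts.astype(int), "empty": counts == 0}
    )


def write_shared_tsv(shared: SharedMarkerSet, path: str | Path) -> None:
    out = shared.frame.copy()
    out.insert(1, "chrom", shared.chromosome)
    out.to_csv(path, sep="\t", index=False)
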