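"""Per-chromosome missing-call statistics.

On an array whose probes were designed against wheat, a marker whose wheat
target has been replaced by alien chromatin simply stops calling (unless
the probe cross-hybridizes with the alien homoeolog).  The per-sample,
per-chromosome missing-call ratio is therefore the primary screen
statistic: a whole-chromosome substitution shows up as one chromosome with
~60% missing against a ~1% background.

Ratios are rendered as one-decimal percentages with banker's rounding
(round-half-even), computed in exact decimal arithmetic from the count
pair so the printed table is a pure function of (n_missing, n_mapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, SampleLookupError
from .genotypes import GenotypeMatrix, MarkerMap, check_map_in_genotypes


def percent_one_decimal(numerator: int, denominator: int) -> str:
    """Render ``numerator/denominator`` as e.g. ``'59.0%'``.

    One decimal place, round-half-even, exact decimal arithmetic.
    """
    if denominator <= 0:
        raise InputError("denominator must be > 0")
    value = (Decimal(numerator) / Decimal(denominator) * 100).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN
    )
    return f"{value}%"


@dataclass
class ChromosomeMissingnessSummary:
    """Mapped/missing marker counts per chromosome for one sample.

    ``frame`` columns: chromosome, n_mapped, n_missing, missing_ratio
    (NaN where n_mapped == 0).  ``discrepancies`` lists markers placed on
    the reference but absent from the genotype table; they are excluded
    from every denominator.
    """

    sample: str
    frame: pd.DataFrame
    discrepancies: list[str] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls, sample: str, counts: Mapping[str, tuple[int, int]]
    ) -> "ChromosomeMissingnessSummary":
        """Build directly from {chromosome: (n_mapped, n_missing)} pairs."""
        rows = []
        for chrom, (n_mapped, n_missing) in counts.items():
            if not 0 <= n_missing <= n_mapped:
                raise InputError(
                    f"{chrom}: need 0 <= n_missing <= n_mapped, got {n_missing}/{n_mapped}"
                )
            rows.append(
                {
                    "chromosome": chrom,
                    "n_mapped": n_mapped,
                    "n_missing": n_missing,
                    "missing_ratio": n_missing / n_mapped if n_mapped else np.nan,
                }
            )
        frame = pd.DataFrame(rows).sort_values("chromosome").reset_index(drop=True)
        return cls(sample=sample, frame=frame)

    @property
    def total_mapped(self) -> int:
        return int(self.frame["n_mapped"].sum())

    @property
    def total_missing(self) -> int:
        return int(self.frame["n_missing"].sum())

    def ratio(self, chrom: str) -> float:
        row = self.frame[self.frame["chromosome"] == chrom]
        if row.empty:
            raise SampleLookupError(f"unknown chromosome {chrom!r}")
        return float(row["missing_ratio"].iloc[0])


def summarize_missingness(
    genotypes: GenotypeMatrix, marker_map: MarkerMap, sample: str
) -> ChromosomeMissingnessSummary:
    """Count mapped and missing markers per chromosome for one sample."""
    calls = genotypes.sample_calls(sample)  # raises for unknown sample
    placed, discrepancies = check_map_in_genotypes(marker_map, genotypes)
    missing = (
        calls.reindex(placed["marker"]).to_numpy(dtype=object) == "NC"
    )
    frame = (
        pd.DataFrame({"chromosome": placed["chrom"].to_numpy(), "missing": missing})
        .groupby("chromosome", sort=True)
        .agg(n_mapped=("missing", "size"), n_missing=("missing", "sum"))
        .reset_index()
    )
    frame["n_missing"] = frame["n_missing"].astype(int)
    frame["missing_ratio"] = np.where(
        frame["n_mapped"] > 0, frame["n_missing"] / frame["n_mapped"], np.nan
    )
    return ChromosomeMissingnessSummary(sample=sample, frame=frame, discrepancies=discrepancies)


def hybridization_rate(genotypes: GenotypeMatrix, alien_sample: str) -> float:
    """Fraction of *all* markers (mapped or not) with a call in the alien
    donor — the cross-hybridization rate of the array with the alien
    genome."""
    calls = genotypes.sample_calls(alien_sample)
    return float((calls.to_numpy(dtype=object) != "NC").mean())


def render_table1(summaries: Sequence[ChromosomeMissingnessSummary]) -> pd.DataFrame:
    """Format per-line missingness as the screen's standard report table.

    One row per chromosome; a shared mapped-marker ``Number`` column, then
    per sample its missing ``Number`` and one-decimal percentage ``Ratio``.
    All summaries must derive from the same marker map (identical
    chromosome sets and mapped counts).
    """
    if not summaries:
        raise InputError("no summaries given")
    base = summaries[0].frame[["chromosome", "n_mapped"]]
    table = base.rename(columns={"chromosome": "Chromosome", "n_mapped": "Number"}).copy()
    for summ in summaries:
        f = summ.frame
        if list(f["chromosome"]) != list(base["chromosome"]) or list(f["n_mapped"]) != list(
            base["n_mapped"]
        ):
            raise ConsistencyError(
                f"summary for sample {summ.sample!r} does not share the marker map "
                "of the first summary"
            )
        table[f"{summ.sample} Number"] = f["n_missing"].to_numpy()
        table[f"{summ.sample} Ratio"] = [
            percent_one_decimal(m, n) if n > 0 else "NA"
            for m, n in zip(f["n_missing"], f["n_mapped"])
        ]
    return table


def write_table1(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
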