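"""Model/Results facade over the substitution screen.

:class:`SubstitutionScreen` bundles a genotype matrix and a marker map
with the screening policy (window spec, caller thresholds); ``fit()``
runs missingness summaries, window scans and the caller for every queried
sample and returns a :class:`SubstitutionScreenResults` carrying the
calls, per-chromosome statistics and tracks, with a ``summary()`` table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .caller import CallerParams, SubstitutionCall, call_sample, cohort_report
from .genotypes import GenotypeMatrix, MarkerMap
from .missingness import (
    ChromosomeMissingnessSummary,
    hybridization_rate,
    render_table1,
    summarize_missingness,
)
from .windows import WindowRatioTrack, WindowSpec, scan_chromosome


class SubstitutionScreen:
    """Screen a cohort of wheat/alien derivatives for whole-chromosome
    substitutions from SNP-array missingness.

    Parameters
    ----------
    genotypes, marker_map
        The call matrix and the marker placements.
    samples
        Samples to screen; defaults to every sample in the matrix.
    alien_sample
        Optional donor sample used only for the cross-hybridization rate.
    chromosome_lengths
        bp per chromosome; defaults to the maximum placed position.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        marker_map: MarkerMap,
        *,
        samples: Sequence[str] | None = None,
        alien_sample: str | None = None,
        chromosome_lengths: Mapping[str, int] | None = None,
        window_spec: WindowSpec = WindowSpec(),
        caller_params: CallerParams = CallerParams(),
    ):
        self.genotypes = genotypes
        self.marker_map = marker_map
        self.samples = list(samples) if samples is not None else genotypes.samples
        self.alien_sample = alien_sample
        self.chromosome_lengths = dict(
            chromosome_lengths
            if chromosome_lengths is not None
            else marker_map.chromosome_lengths_from_markers()
        )
        self.window_spec = window_spec
        self.caller_params = caller_params

    @classmethod
    def from_files(
        cls,
        genotype_tsv: str | Path,
        map_tsv: str | Path,
        **kwargs,
    ) -> "SubstitutionScreen":
        return cls(GenotypeMatrix.from_tsv(genotype_tsv), MarkerMap.from_tsv(map_tsv), **kwargs)

    def fit(self) -> "SubstitutionScreenResults":
        summaries: dict[str, ChromosomeMissingnessSummary] = {}
        tracks: dict[str, dict[str, WindowRatioTrack]] = {}
        calls: list[SubstitutionCall] = []
        for sample in self.samples:
            summary = summarize_missingness(self.genotypes, self.marker_map, sample)
            sample_tracks = {
                chrom: scan_chromosome(
                    self.genotypes,
                    self.marker_map,
                    sample,
                    chrom,
                    self.window_spec,
                    chromosome_length=int(self.chromosome_lengths[chrom]),
                )
                for chrom in summary.frame["chromosome"]
            }
            summaries[sample] = summary
            tracks[sample] = sample_tracks
            calls.append(call_sample(summary, sample_tracks, self.caller_params))
        hyb = (
            hybridization_rate(self.genotypes, self.alien_sample)
            if self.alien_sample is not None
            else None
        )
        return SubstitutionScreenResults(self, calls, summaries, tracks, hyb)


class SubstitutionScreenResults:
    """Fitted screen: per-sample calls, summaries and window tracks."""

    def __init__(
        self,
        model: SubstitutionScreen,
        calls: list[SubstitutionCall],
        summaries: dict[str, ChromosomeMissingnessSummary],
        tracks: dict[str, dict[str, WindowRatioTrack]],
        hybridization_rate: float | None,
    ):
        self.model = model
        self.calls = calls
        self.summaries = summaries
        self.tracks = tracks
        self.hybridization_rate = hybridization_rate

    @property
    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.calls]).drop(columns=["params"])

    def missingness_table(self) -> pd.DataFrame:
        """The per-chromosome missing-count report for every sample."""
        return render_table1([self.summaries[s] for s in self.model.samples])

    def track(self, sample: str, chromosome: str) -> WindowRatioTrack:
        return self.tracks[sample][chromosome]

    def to_report(self) -> dict:
        report = cohort_report(self.calls, __version__)
        if self.hybridization_rate is not None:
            report["alien_hybridization_rate"] = self.hybridization_rate
        return report

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), sort_keys=True, indent=1))

    def summary(self) -> str:
        """Plain-text overview in the style of a fitted-model summary."""
        lines = []
        title = "Alien chromosome substitution screen"
        lines.append(title.center(78))
        lines.append("=" * 78)
        lines.append(
            f"Markers mapped: {self.model.marker_map.n_markers:>8}    "
            f"Samples screened: {len(self.calls):>3}    "
            f"Window: {self.model.window_spec.window_size // 10**6} Mb / "
            f"step {self.model.window_spec.step // 10**6} Mb"
        )
        if self.hybridization_rate is not None:
            lines.append(
                f"Alien donor ({self.model.alien_sample}) hybridization rate: "
                f"{100 * self.hybridization_rate:.1f}%"
            )
        lines.append("-" * 78)
        lines.append(
            f"{'Sample':<12}{'Verdict':<17}{'Chrom':<7}{'Missing':>9}"
            f"{'Bg med':>9}{'Fold':>9}{'Coverage':>10}"
        )
        for c in self.calls:
            fold = "inf" if np.isinf(c.fold_over_background) else f"{c.fold_over_background:.1f}"
            cov = "NA" if np.isnan(c.coverage_fraction) else f"{c.coverage_fraction:.3f}"
            lines.append(
                f"{c.sample:<12}{c.verdict:<17}{c.called_chromosome or '-':<7}"
                f"{c.missing_ratio:>9.3f}{c.background_median:>9.3f}{fold:>9}{cov:>10}"
            )
        lines.append("=" * 78)
        p = self.model.caller_params
        lines.append(
            f"Thresholds: missing ratio >= {p.min_missing_ratio}, fold over median >= "
            f"{p.min_fold_over_background}, coverage >= {p.min_coverage_fraction} "
            f"at window ratio <= {p.depressed_threshold}"
        )
        return "\n".join(lines)
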