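"""Decision rule for whole-chromosome substitution from chip missingness.

The evidence for a substitution is (i) one chromosome whose missing-call
ratio is both large in absolute terms and many-fold above the background
of the other chromosomes, and (ii) marker loss spread along the whole
chromosome rather than one segment.  The caller formalizes this as three
gates on the candidate chromosome (the one with the maximum missing
ratio):

* ``missing_ratio >= min_missing_ratio`` (default 0.40);
* ``missing_ratio / median(other chromosomes) >= min_fold_over_background``
  (default 5; the median is robust to a couple of divergent chromosomes
  with elevated background missingness);
* ``coverage_fraction >= min_coverage_fraction`` (default 0.8) of defined
  windows depressed below ``depressed_threshold`` (default 0.7).

Verdicts: ``substitution`` when all three gates pass; ``ambiguous`` when
the ratio gates pass but the coverage gate fails (segmental-introgression
suspect) or the maximum ratio is tied between chromosomes; otherwise
``no_substitution``.  Thresholds are policy, echoed in every call so a
report is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix, MarkerMap
from .missingness import ChromosomeMissingnessSummary, summarize_missingness
from .windows import WindowRatioTrack, WindowSpec, coverage_fraction, scan_chromosome


@dataclass(frozen=True)
class CallerParams:
    min_missing_ratio: float = 0.40
    min_fold_over_background: float = 5.0
    min_coverage_fraction: float = 0.8
    depressed_threshold: float = 0.7

    def __post_init__(self):
        for name in ("min_missing_ratio", "min_coverage_fraction", "depressed_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.min_fold_over_background < 1.0:
            raise InputError("min_fold_over_background must be >= 1")


@dataclass
class SubstitutionCall:
    sample: str
    verdict: str  # substitution | no_substitution | ambiguous
    called_chromosome: str | None
    missing_ratio: float
    background_median: float
    fold_over_background: float
    coverage_fraction: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        # NaN is not valid JSON; report nulls instead
        for k, v in d.items():
            if isinstance(v, float) and np.isnan(v):
                d[k] = None
        return d


def call_sample(
    summary: ChromosomeMissingnessSummary,
    tracks: Mapping[str, WindowRatioTrack],
    params: CallerParams = CallerParams(),
) -> SubstitutionCall:
    """Call one sample from its missingness summary and window tracks."""
    frame = summary.frame[summary.frame["missing_ratio"].notna()]
    if frame.empty:
        raise InputError(f"sample {summary.sample!r}: empty missingness summary")
    ratios = frame.set_index("chromosome")["missing_ratio"]
    top = float(ratios.max())
    candidates = list(ratios.index[ratios == top])
    others = ratios.drop(candidates[0])
    background = float(others.median()) if len(others) else 0.0
    if top == 0.0:
        fold = 0.0
    elif background == 0.0:
        fold = float("inf")
    else:
        fold = top / background

    if len(candidates) > 1:
        # tied maxima: never pick one arbitrarily
        return SubstitutionCall(
            sample=summary.sample,
            verdict="ambiguous",
            called_chromosome=None,
            missing_ratio=top,
            background_median=background,
            fold_over_background=fold,
            coverage_fraction=float("nan"),
            params=asdict(params),
        )

    candidate = candidates[0]
    ratio_pass = top >= params.min_missing_ratio and fold >= params.min_fold_over_background
    track = tracks.get(candidate)
    if track is not None and not track.defined.empty:
        cov = coverage_fraction(track, params.depressed_threshold)
    else:
        cov = float("nan")
    coverage_pass = not np.isnan(cov) and cov >= params.min_coverage_fraction

    if ratio_pass and coverage_pass:
        verdict = "substitution"
    elif ratio_pass:
        verdict = "ambiguous"
    else:
        verdict = "no_substitution"
    return SubstitutionCall(
        sample=summary.sample,
        verdict=verdict,
        called_chromosome=candidate if verdict != "no_substitution" else None,
        missing_ratio=top,
        background_median=background,
        fold_over_background=fold,
        coverage_fraction=cov,
        params=asdict(params),
    )


def call_cohort(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    samples: Sequence[str],
    params: CallerParams = CallerParams(),
    window_spec: WindowSpec = WindowSpec(),
    chromosome_lengths: Mapping[str, int] | None = None,
) -> list[SubstitutionCall]:
    """One call per sample, each from its own summary and window tracks."""
    if chromosome_lengths is None:
        chromosome_lengths = marker_map.chromosome_lengths_from_markers()
    calls = []
    for sample in samples:
        summary = summarize_missingness(genotypes, marker_map, sample)
        tracks = {
            chrom: scan_chromosome(
                genotypes,
                marker_map,
                sample,
                chrom,
                window_spec,
                chromosome_length=int(chromosome_lengths[chrom]),
            )
            for chrom in summary.frame["chromosome"]
        }
        calls.append(call_sample(summary, tracks, params))
    return calls


def cohort_report(calls: Sequence[SubstitutionCall], version: str) -> dict:
    """JSON-ready report; ``any_ambiguous`` drives the CLI exit status."""
    return {
        "software": {"name": "subchrom", "version": version},
        "n_samples": len(calls),
        "any_ambiguous": any(c.verdict == "ambiguous" for c in calls),
        "calls": [c.to_dict() for c in calls],
    }
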