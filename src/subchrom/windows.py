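"""Sliding-window observed/expected marker density along a chromosome.

For a sample and a chromosome, each 10 Mb window (stepped by 1 Mb) gets
``n_expected`` = mapped markers in the window and ``n_observed`` = those
with a call in the sample; a substitution line shows the ratio uniformly
depressed along the whole substituted chromosome, which distinguishes a
whole-chromosome event from a segmental introgression.

Coordinate convention, centralized here: windows are 0-based half-open
``[start, start + window_size)``; marker positions are 1-based; a marker
at position p falls in a window iff ``start < p <= end``.  The final
partial window at the chromosome end is kept (flagged undefined if it
holds fewer than ``min_expected`` markers, like any sparse window).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SampleLookupError, UndefinedResultError
from .genotypes import GenotypeMatrix, MarkerMap, check_map_in_genotypes


@dataclass(frozen=True)
class WindowSpec:
    window_size: int = 10_000_000
    step: int = 1_000_000
    min_expected: int = 5

    def __post_init__(self):
        if self.window_size <= 0 or self.step <= 0:
            raise InputError("window_size and step must be > 0")
        if self.step > self.window_size:
            raise InputError("step must be <= window_size")
        if self.min_expected < 0:
            raise InputError("min_expected must be >= 0")


@dataclass
class WindowRatioTrack:
    """Per-window counts and observed/expected ratio for one chromosome.

    ``frame`` columns: start, end (0-based half-open), n_expected,
    n_observed, ratio (NaN = undefined, i.e. n_expected < min_expected).
    """

    chromosome: str
    frame: pd.DataFrame

    @property
    def defined(self) -> pd.DataFrame:
        return self.frame[self.frame["ratio"].notna()]


def window_starts(chromosome_length: int, spec: WindowSpec) -> np.ndarray:
    """0-based window starts: every multiple of ``step`` below the
    chromosome length."""
    if chromosome_length <= 0:
        raise InputError("chromosome_length must be > 0")
    return np.arange(0, chromosome_length, spec.step, dtype=np.int64)


def _count_in_windows(
    positions: np.ndarray, starts: np.ndarray, window_size: int
) -> np.ndarray:
    # membership: start < p <= start + window_size, positions sorted 1-based
    ends = starts + window_size
    return (
        np.searchsorted(positions, ends, side="right")
        - np.searchsorted(positions, starts, side="right")
    )


def scan_chromosome(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    sample: str,
    chromosome: str,
    spec: WindowSpec = WindowSpec(),
    chromosome_length: int | None = None,
    parents: Sequence[str] | None = None,
) -> WindowRatioTrack:
    """Observed/expected marker counts in sliding windows.

    By default "expected" is every mapped marker in the window; passing
    *parents* restricts the expected set to markers called (non-NC) in all
    of the given parent samples, for data where the parents themselves
    fail to call a fraction of the array.
    """
    calls = genotypes.sample_calls(sample)
    placed, _ = check_map_in_genotypes(marker_map, genotypes)
    on_chrom = placed[placed["chrom"] == chromosome]
    if chromosome not in set(marker_map.frame["chrom"]):
        raise SampleLookupError(f"unknown chromosome {chromosome!r}")
    if parents:
        keep = np.ones(len(on_chrom), dtype=bool)
        for parent in parents:
            pcalls = genotypes.sample_calls(parent)
            keep &= pcalls.reindex(on_chrom["marker"]).to_numpy(dtype=object) != "NC"
        on_chrom = on_chrom[keep]
    positions = on_chrom["pos"].to_numpy()  # already sorted within chromosome
    observed_mask = calls.reindex(on_chrom["marker"]).to_numpy(dtype=object) != "NC"
    obs_positions = positions[observed_mask]

    if chromosome_length is None:
        chromosome_length = int(positions.max()) if len(positions) else spec.window_size
    if len(positions) and chromosome_length < int(positions.max()):
        raise InputError(
            f"chromosome_length {chromosome_length} below the maximum marker "
            f"position {int(positions.max())} on {chromosome}"
        )
    starts = window_starts(chromosome_length, spec)
    n_expected = _count_in_windows(positions, starts, spec.window_size)
    n_observed = _count_in_windows(obs_positions, starts, spec.window_size)
    ratio = np.where(
        n_expected >= max(spec.min_expected, 1), n_observed / np.maximum(n_expected, 1), np.nan
    )
    frame = pd.DataFrame(
        {
            "start": starts,
            "end": starts + spec.window_size,
            "n_expected": n_expected.astype(int),
            "n_observed": n_observed.astype(int),
            "ratio": ratio,
        }
    )
    return WindowRatioTrack(chromosome=chromosome, frame=frame)


def coverage_fraction(track: WindowRatioTrack, depressed_threshold: float) -> float:
    """Fraction of defined windows with ratio <= *depressed_threshold* —
    the 'whole chromosome' test: near 1.0 when marker loss spans the
    entire chromosome."""
    defined = track.defined
    if defined.empty:
        raise UndefinedResultError(
            f"track for {track.chromosome} has no defined windows"
        )
    return float((defined["ratio"] <= depressed_threshold).mean())


# -- serialization and plotting ------------------------------------------

def export_track(
    track: WindowRatioTrack,
    bed_path: str | Path,
    plot_path: str | Path | None = None,
) -> None:
    """Write the track as BED4 (chrom, start, end, ratio; 0-based
    half-open; 'NA' for undefined windows) and optionally a step plot.

    Sliding windows overlap; intervals are emitted as-is, never merged.
    """
    frame = track.frame
    with open(bed_path, "w") as fh:
        for start, end, ratio in zip(frame["start"], frame["end"], frame["ratio"]):
            val = "NA" if np.isnan(ratio) else f"{ratio:.6f}"
            fh.write(f"{track.chromosome}\t{start}\t{end}\t{val}\n")
    if plot_path is not None:
        plot_track(track, plot_path)


def read_track_bed(path: str | Path) -> WindowRatioTrack:
    frame = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "ratio"], na_values=["NA"]
    )
    chromosome = str(frame["chrom"].iloc[0]) if len(frame) else ""
    return WindowRatioTrack(
        chromosome=chromosome,
        frame=frame[["start", "end", "ratio"]].copy(),
    )


def plot_track(track: WindowRatioTrack, path: str | Path) -> None:
    """Step plot of the window ratio along the chromosome (Mb axis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = track.frame
    mid = (frame["start"] + frame["end"]) / 2e6
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.step(mid, frame["ratio"], where="mid", lw=1.2)
    ax.set_xlabel(f"{track.chromosome} position (Mb)")
    ax.set_ylabel("observed / expected")
    ax.set_ylim(-0.02, 1.05)
    ax.set_title(track.chromosome)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150, metadata={"Software": None})
    plt.close(fig)
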