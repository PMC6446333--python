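"""In-memory containers for array genotype calls and marker placements.

The two central objects are thin, validated wrappers around pandas
DataFrames:

* :class:`GenotypeMatrix` — calls for markers x samples, each cell one of
  ``AA``, ``AB``, ``BB`` or ``NC`` (no call).  A missing call is the signal
  this whole pipeline is built on: on an array designed against wheat, a
  NoCall is read as absence of the hybridizing wheat target sequence.
* :class:`MarkerMap` — the placement of each marker on the reference
  assembly (chromosome, 1-based bp position).  It defines the "expected"
  marker universe for every per-chromosome and per-window denominator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, SampleLookupError

CALL_STATES = ("AA", "AB", "BB", "NC")

#: spellings accepted as "no call" when reading genotype tables
DEFAULT_MISSING_SPELLINGS = ("NC", "NoCall", "NOCALL", "NO CALL", "--", "NA", "N/A", "")


class GenotypeMatrix:
    """Genotype calls for a set of samples at a set of markers.

    Parameters
    ----------
    calls
        DataFrame indexed by marker id with one column per sample; every
        cell must be one of ``AA``, ``AB``, ``BB``, ``NC``.
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.index.has_duplicates:
            raise InputError("duplicate marker ids in genotype matrix")
        if calls.columns.has_duplicates:
            raise InputError("duplicate sample ids in genotype matrix")
        values = calls.to_numpy(dtype=object)
        bad = ~np.isin(values, CALL_STATES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"invalid call state {values[i, j]!r} at marker "
                f"{calls.index[i]!r}, sample {calls.columns[j]!r}"
            )
        self.calls = calls.astype(object)

    # -- basic accessors -------------------------------------------------
    @property
    def markers(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.calls.index)

    def sample_calls(self, sample: str) -> pd.Series:
        if sample not in self.calls.columns:
            raise SampleLookupError(f"unknown sample {sample!r}")
        return self.calls[sample]

    def is_missing(self, sample: str) -> pd.Series:
        """Boolean series: True where the sample has no call (``NC``)."""
        return self.sample_calls(sample) == "NC"

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        missing_spellings: Sequence[str] = DEFAULT_MISSING_SPELLINGS,
    ) -> "GenotypeMatrix":
        """Read a marker-by-sample call table (rows = markers).

        Any cell matching one of *missing_spellings* (case-sensitive, as
        listed) is normalized to ``NC``.
        """
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        frame = frame.replace({s: "NC" for s in missing_spellings})
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="marker")


class MarkerMap:
    """Markers placed on a reference: columns ``marker``, ``chrom``, ``pos``.

    Positions are 1-based, forward strand, inclusive.  Extra columns
    (``strand``, ``mismatches``, ``evalue``) produced by the probe-mapping
    stage are carried through untouched.  Rows are kept in a canonical
    (chrom, pos, marker) order so every downstream summary is invariant to
    the input row order.
    """

    REQUIRED = ("marker", "chrom", "pos")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise InputError(f"marker map lacks required column(s) {missing}")
        frame = frame.copy()
        frame["pos"] = frame["pos"].astype(np.int64)
        if (frame["pos"] < 1).any():
            bad = frame.loc[frame["pos"] < 1, "marker"].iloc[0]
            raise InputError(f"marker {bad!r} has position < 1")
        if frame["marker"].duplicated().any():
            dup = frame.loc[frame["marker"].duplicated(), "marker"].iloc[0]
            raise InputError(f"duplicate marker id {dup!r} in marker map")
        self.frame = frame.sort_values(
            ["chrom", "pos", "marker"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.frame["chrom"].unique())

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def markers_on(self, chrom: str) -> pd.DataFrame:
        if chrom not in set(self.frame["chrom"]):
            raise SampleLookupError(f"unknown chromosome {chrom!r}")
        return self.frame[self.frame["chrom"] == chrom]

    def chromosome_lengths_from_markers(self) -> dict[str, int]:
        """Fallback chromosome lengths: the maximum placed position."""
        return self.frame.groupby("chrom")["pos"].max().astype(int).to_dict()

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def check_map_in_genotypes(
    marker_map: MarkerMap, genotypes: GenotypeMatrix
) -> tuple[pd.DataFrame, list[str]]:
    """Split a map into (rows present in G, marker ids absent from G).

    Markers placed on the reference but absent from the call table cannot
    contribute to any denominator; they are reported, never silently
    dropped.
    """
    present = marker_map.frame["marker"].isin(genotypes.markers)
    discrepancies = marker_map.frame.loc[~present, "marker"].tolist()
    return marker_map.frame[present], discrepancies
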