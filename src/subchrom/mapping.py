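"""Placement of array probe flanking sequences on a reference assembly.

Array markers are short (35–71 nt) flanking sequences.  Placement uses
exhaustive ungapped matching: every full-length occurrence of the query
(forward or reverse complement) with at most ``max_mismatch`` mismatches
is a hit.  A one-base mismatch allowance precludes gaps, so no alignment
machinery beyond a sliding comparison is needed, and the search is exact —
equivalent to a position-by-position scan.

Each hit is scored ``matches * match_score + mismatches * mismatch_score``
and assigned a Karlin–Altschul expect value E = K * m * n * exp(-lambda*S)
(m = query length, n = total reference length).  The E-value acts purely
as a pass/fail gate; the defaults for lambda and K correspond to ungapped
+1/−2 nucleotide scoring.

A marker is placed only when it has a unique best passing hit (strictly
fewest mismatches); markers with tied best hits are rejected as ambiguous
so that each contributes to exactly one chromosome's denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import InputError
from .genotypes import MarkerMap

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

# query/reference byte-code tables; codes for unknown bases differ between
# the two so that an N (or any ambiguity code) never matches anything,
# including another N
_Q_UNKNOWN, _R_UNKNOWN = 200, 201
_QUERY_CODES = np.full(256, _Q_UNKNOWN, dtype=np.uint8)
_REF_CODES = np.full(256, _R_UNKNOWN, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    for _c in (_b, _b + 32):  # upper and lower case
        _QUERY_CODES[_c] = _i
        _REF_CODES[_c] = _i


@dataclass(frozen=True)
class FlankingSequence:
    """A marker's flanking sequence: id plus an IUPAC DNA string."""

    marker: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"marker {self.marker!r}: empty sequence")
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise InputError(
                f"marker {self.marker!r}: invalid character(s) {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class MappingParams:
    max_mismatch: int = 1
    evalue_threshold: float = 1e-10
    lam: float = 1.28
    K: float = 0.46
    match_score: int = 1
    mismatch_score: int = -2
    require_unique_best: bool = True

    def __post_init__(self):
        if self.max_mismatch < 0:
            raise InputError("max_mismatch must be >= 0")
        if self.evalue_threshold <= 0:
            raise InputError("evalue_threshold must be > 0")
        if self.lam <= 0 or self.K <= 0:
            raise InputError("lambda and K must be > 0")


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int  # 1-based coordinate of the hit's first base on the forward strand
    strand: str  # '+' or '-'
    mismatches: int
    score: int
    evalue: float


def evalue(score: int, query_len: int, reference_len: int, params: MappingParams) -> float:
    """Karlin–Altschul expect value ``K * m * n * exp(-lambda * score)``."""
    if query_len < 1 or reference_len < 1:
        raise InputError("query_len and reference_len must be >= 1")
    return params.K * query_len * reference_len * math.exp(-params.lam * score)


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mismatch_profile(ref_codes: np.ndarray, q_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the query at every ungapped offset of the reference."""
    n, m = len(ref_codes), len(q_codes)
    if m > n:
        return np.empty(0, dtype=np.int32)
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        counts += ref_codes[j : j + n - m + 1] != q_codes[j]
    return counts


def find_hits(
    query: FlankingSequence,
    reference: Mapping[str, str],
    params: MappingParams = MappingParams(),
) -> list[Hit]:
    """Every full-length ungapped occurrence of *query* (both strands) in
    *reference* with at most ``params.max_mismatch`` mismatches.

    Exhaustive by construction; a query longer than every reference
    sequence simply yields no hits.  Hits are sorted by (mismatches,
    chrom, start, strand).
    """
    if not reference:
        raise InputError("reference is empty")
    m = len(query.sequence)
    total_len = sum(len(s) for s in reference.values())
    fwd = _encode(query.sequence.upper(), _QUERY_CODES)
    rev = _encode(reverse_complement(query.sequence.upper()), _QUERY_CODES)
    hits: list[Hit] = []
    for chrom in reference:
        ref_codes = _encode(str(reference[chrom]).upper(), _REF_CODES)
        for strand, q_codes in (("+", fwd), ("-", rev)):
            profile = _mismatch_profile(ref_codes, q_codes)
            for i in np.nonzero(profile <= params.max_mismatch)[0]:
                mm = int(profile[i])
                score = (m - mm) * params.match_score + mm * params.mismatch_score
                hits.append(
                    Hit(
                        chrom=chrom,
                        start=int(i) + 1,
                        strand=strand,
                        mismatches=mm,
                        score=score,
                        evalue=evalue(score, m, total_len, params),
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits


@dataclass
class RejectedMarker:
    marker: str
    reason: str  # no_hit | evalue_fail | ambiguous


def build_marker_map(
    queries: Iterable[FlankingSequence],
    reference: Mapping[str, str],
    params: MappingParams = MappingParams(),
) -> tuple[MarkerMap, list[RejectedMarker]]:
    """Place each marker at its unique best passing hit.

    A marker is placed iff at least one hit passes both the mismatch and
    E-value gates and (under ``require_unique_best``) a single hit has
    strictly fewer mismatches than every other passing hit.  Rejected
    markers carry a reason: ``no_hit`` (nothing within the mismatch
    allowance), ``evalue_fail`` (hits exist, none passes the gate), or
    ``ambiguous`` (tied best hits).
    """
    rows = []
    rejected: list[RejectedMarker] = []
    for query in queries:
        hits = find_hits(query, reference, params)
        if not hits:
            rejected.append(RejectedMarker(query.marker, "no_hit"))
            continue
        passing = [h for h in hits if h.evalue <= params.evalue_threshold]
        if not passing:
            rejected.append(RejectedMarker(query.marker, "evalue_fail"))
            continue
        best_mm = passing[0].mismatches  # sorted by mismatches asc
        best = [h for h in passing if h.mismatches == best_mm]
        if params.require_unique_best and len(best) > 1:
            rejected.append(RejectedMarker(query.marker, "ambiguous"))
            continue
        hit = best[0]
        rows.append(
            {
                "marker": query.marker,
                "chrom": hit.chrom,
                "pos": hit.start,
                "strand": hit.strand,
                "mismatches": hit.mismatches,
                "evalue": hit.evalue,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["marker", "chrom", "pos", "strand", "mismatches", "evalue"]
    )
    if frame.empty:
        frame = frame.astype({"pos": np.int64})
    return MarkerMap(frame), rejected


# -- FASTA I/O -----------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences from a FASTA file (ids truncated at first whitespace)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_query_fasta(path: str | Path) -> list[FlankingSequence]:
    return [
        FlankingSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_rejects_tsv(rejected: list[RejectedMarker], path: str | Path) -> None:
    pd.DataFrame(
        [(r.marker, r.reason) for r in rejected], columns=["marker", "reason"]
    ).to_csv(path, sep="\t", index=False)
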