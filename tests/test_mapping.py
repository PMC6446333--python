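"""Probe placement: ungapped scan, E-value gate, unique-best policy."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from subchrom import FlankingSequence, MappingParams, build_marker_map, evalue, find_hits
from subchrom.errors import InputError

from helpers import mutate_one_base, naive_find_hits, random_dna, revcomp

P0 = MappingParams(max_mismatch=0, evalue_threshold=1.0)
P1 = MappingParams(max_mismatch=1, evalue_threshold=1.0)


def test_exact_self_match_single_forward_hit():
    hits = find_hits(FlankingSequence("q", "ACGTACGG"), {"c1": "ACGTACGG"}, P0)
    assert len(hits) == 1
    h = hits[0]
    assert (h.chrom, h.start, h.strand, h.mismatches) == ("c1", 1, "+", 0)


def test_palindromic_query_reported_on_both_strands():
    # a reverse-complement palindrome legitimately matches both strands
    hits = find_hits(FlankingSequence("q", "ACGTACGT"), {"c1": "ACGTACGT"}, P0)
    assert [(h.start, h.strand) for h in hits] == [(1, "+"), (1, "-")]


def test_reverse_complement_hit_on_minus_strand():
    query = "ACCGTTAGGCAT"
    ref = "TTTT" + revcomp(query) + "GGGG"
    hits = find_hits(FlankingSequence("q", query), {"c1": ref}, P0)
    assert [(h.start, h.strand, h.mismatches) for h in hits] == [(5, "-", 0)]


def test_n_in_query_counts_as_mismatch_never_matches():
    ref = {"c1": "AAAACGTACGTAAAA"}
    with_n = FlankingSequence("q", "ACGTNCGT")
    assert find_hits(with_n, ref, P0) == []
    hits = find_hits(with_n, ref, P1)
    assert hits and all(h.mismatches == 1 for h in hits)
    # N in the reference does not match an N in the query either
    assert find_hits(FlankingSequence("q", "ANGT"), {"c1": "ANGT"}, P0) == []


def test_invalid_query_alphabet_rejected():
    with pytest.raises(InputError):
        FlankingSequence("q", "ACGT-ACGT")
    with pytest.raises(InputError):
        FlankingSequence("q", "")


def test_query_longer_than_reference_yields_no_hits():
    assert find_hits(FlankingSequence("q", "ACGTACGTACGT"), {"c1": "ACGT"}, P1) == []


# -- E-value --------------------------------------------------------------

def test_evalue_closed_form_frozen_value():
    params = MappingParams(lam=1.28, K=0.46)
    # K*m*n*exp(-lambda*S) at S=50, m=50, n=1e6, computed independently
    assert evalue(50, 50, 10**6, params) == pytest.approx(3.688765048261867e-21, rel=1e-12)


def test_evalue_monotone_in_score_and_linear_in_lengths():
    params = MappingParams()
    scores = [10, 20, 40, 80]
    values = [evalue(s, 50, 10**6, params) for s in scores]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert evalue(30, 50, 2 * 10**6, params) == pytest.approx(
        2 * evalue(30, 50, 10**6, params)
    )
    assert evalue(30, 100, 10**6, params) == pytest.approx(
        2 * evalue(30, 50, 10**6, params)
    )


def test_evalue_rejects_nonpositive_lengths():
    with pytest.raises(InputError):
        evalue(10, 0, 100, MappingParams())


# -- oracle equivalence ----------------------------------------------------

def test_find_hits_matches_bruteforce_scanner_on_planted_queries():
    """Planted exact and one-mismatch 50-mers over a random reference give
    identical hit lists to a position-by-position python scanner."""
    rng = np.random.default_rng(11)
    reference = {"c1": random_dna(30_000, rng), "c2": random_dna(20_000, rng)}
    queries = []
    for k in range(12):
        chrom = "c1" if k % 2 == 0 else "c2"
        start = int(rng.integers(0, len(reference[chrom]) - 50))
        original = reference[chrom][start : start + 50]
        queries.append(FlankingSequence(f"plant{k}", mutate_one_base(original, rng)))
    for k in range(6):
        queries.append(FlankingSequence(f"rand{k}", random_dna(50, rng)))
    for query in queries:
        got = [(h.chrom, h.start, h.strand, h.mismatches) for h in find_hits(query, reference, P1)]
        assert got == naive_find_hits(query.sequence, reference, 1), query.marker


# -- build_marker_map ------------------------------------------------------

def _planted_reference_and_queries(rng, n_unique=15, n_dup=4, length=60):
    c1, c2 = random_dna(25_000, rng), random_dna(25_000, rng)
    queries = []
    for k in range(n_unique):
        start = 100 + k * 1500
        queries.append(FlankingSequence(f"uniq{k:02d}", c1[start : start + length]))
    dup_block = ""
    for k in range(n_dup):
        seq = random_dna(length, rng)
        queries.append(FlankingSequence(f"dup{k:02d}", seq))
        dup_block += seq + random_dna(20, rng)
    # the duplicated markers occur once on each chromosome
    reference = {"c1": c1 + dup_block, "c2": c2 + dup_block}
    return reference, queries


def test_unique_markers_placed_duplicates_rejected_ambiguous():
    rng = np.random.default_rng(5)
    reference, queries = _planted_reference_and_queries(rng)
    params = MappingParams(max_mismatch=1, evalue_threshold=1e-10)
    marker_map, rejected = build_marker_map(queries, reference, params)
    placed = set(marker_map.frame["marker"])
    assert placed == {q.marker for q in queries if q.marker.startswith("uniq")}
    assert {r.marker for r in rejected} == {q.marker for q in queries if q.marker.startswith("dup")}
    assert all(r.reason == "ambiguous" for r in rejected)
    # positions are the 1-based first reference base of each planted copy
    row = marker_map.frame[marker_map.frame["marker"] == "uniq00"].iloc[0]
    assert (row["chrom"], row["pos"], row["mismatches"]) == ("c1", 101, 0)


def test_short_query_fails_evalue_gate():
    rng = np.random.default_rng(9)
    ref = {"c1": random_dna(200_000, rng)}
    probe = ref["c1"][500:512]  # 12-mer: max score 12 cannot reach E <= 1e-10
    marker_map, rejected = build_marker_map(
        [FlankingSequence("short", probe)], ref, MappingParams(evalue_threshold=1e-10)
    )
    assert marker_map.n_markers == 0
    assert [r.reason for r in rejected] == ["evalue_fail"]


def test_absent_query_rejected_no_hit():
    rng = np.random.default_rng(10)
    ref = {"c1": random_dna(5_000, rng)}
    _, rejected = build_marker_map(
        [FlankingSequence("ghost", random_dna(60, rng))], ref, MappingParams()
    )
    assert [r.reason for r in rejected] == ["no_hit"]


def test_strand_involution():
    """Mapping the reverse complement of every query gives the same
    placements with the strand flipped."""
    rng = np.random.default_rng(21)
    reference, queries = _planted_reference_and_queries(rng, n_unique=8, n_dup=0)
    params = MappingParams()
    fwd, _ = build_marker_map(queries, reference, params)
    rc = [FlankingSequence(q.marker, revcomp(q.sequence)) for q in queries]
    rev, _ = build_marker_map(rc, reference, params)
    merged = fwd.frame.merge(rev.frame, on="marker", suffixes=("_f", "_r"))
    assert len(merged) == len(fwd.frame)
    assert (merged["chrom_f"] == merged["chrom_r"]).all()
    assert (merged["pos_f"] == merged["pos_r"]).all()
    assert (merged["strand_f"] != merged["strand_r"]).all()


@given(st.floats(min_value=1e-40, max_value=1.0), st.floats(min_value=1e-40, max_value=1.0))
def test_gate_monotonicity_lower_threshold_never_adds_placements(t1, t2):
    lo, hi = sorted([t1, t2])
    rng = np.random.default_rng(3)
    reference, queries = _planted_reference_and_queries(rng, n_unique=5, n_dup=1, length=40)
    strict, _ = build_marker_map(queries, reference, MappingParams(evalue_threshold=lo))
    loose, _ = build_marker_map(queries, reference, MappingParams(evalue_threshold=hi))
    assert set(strict.frame["marker"]) <= set(loose.frame["marker"])
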