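"""Sliding-window observed/expected track: membership, oracle, round trip."""

import numpy as np
import pandas as pd
import pytest

from subchrom import (
    GenotypeMatrix,
    MarkerMap,
    WindowRatioTrack,
    WindowSpec,
    coverage_fraction,
    export_track,
    read_track_bed,
    scan_chromosome,
    summarize_missingness,
)
from subchrom.errors import InputError, UndefinedResultError

from helpers import naive_window_counts

MB = 1_000_000


def toy_chromosome(positions, calls, chrom="4B"):
    markers = [f"m{i}" for i in range(len(positions))]
    mm = MarkerMap(pd.DataFrame({"marker": markers, "chrom": chrom, "pos": positions}))
    G = GenotypeMatrix(
        pd.DataFrame({"S": calls}, index=pd.Index(markers, name="marker"))
    )
    return mm, G


def test_window_spec_validation():
    with pytest.raises(InputError):
        WindowSpec(window_size=0)
    with pytest.raises(InputError):
        WindowSpec(window_size=5, step=6)


def test_track_matches_bruteforce_recount_on_enumerated_fixture():
    rng = np.random.default_rng(42)
    positions = sorted(int(p) for p in rng.integers(1, 30 * MB + 1, size=400))
    calls = [("NC" if rng.random() < 0.3 else "AA") for _ in positions]
    mm, G = toy_chromosome(positions, calls)
    spec = WindowSpec(window_size=10 * MB, step=1 * MB, min_expected=5)
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=30 * MB)
    starts = list(range(0, 30 * MB, MB))
    exp, obs = naive_window_counts(positions, calls, starts, 10 * MB)
    assert list(track.frame["start"]) == starts
    assert list(track.frame["n_expected"]) == exp
    assert list(track.frame["n_observed"]) == obs
    for e, o, r in zip(exp, obs, track.frame["ratio"]):
        if e >= 5:
            assert r == pytest.approx(o / e)
        else:
            assert np.isnan(r)


def test_boundary_membership_half_open_on_one_based_positions():
    # marker at exactly window_size falls in the first partition window;
    # window_size + 1 falls in the second
    mm, G = toy_chromosome([10 * MB, 10 * MB + 1], ["AA", "AA"])
    spec = WindowSpec(window_size=10 * MB, step=10 * MB, min_expected=0)
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=20 * MB)
    assert list(track.frame["n_expected"]) == [1, 1]


def test_interior_marker_counted_once_per_step_offset():
    mm, G = toy_chromosome([15 * MB], ["AA"])
    spec = WindowSpec(window_size=10 * MB, step=1 * MB, min_expected=0)
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=30 * MB)
    assert int(track.frame["n_expected"].sum()) == 10  # window_size / step


def test_fully_called_sample_has_unit_ratio_everywhere_defined():
    positions = list(range(1, 30 * MB, 997_000))
    mm, G = toy_chromosome(positions, ["AA"] * len(positions))
    track = scan_chromosome(G, mm, "S", "4B", WindowSpec(), chromosome_length=30 * MB)
    defined = track.defined
    assert not defined.empty
    assert (defined["ratio"] == 1.0).all()


def test_empty_window_is_flagged_undefined_never_zero_over_zero():
    mm, G = toy_chromosome([1 * MB], ["AA"])
    spec = WindowSpec(window_size=10 * MB, step=10 * MB, min_expected=1)
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=30 * MB)
    assert np.isnan(track.frame["ratio"].iloc[1])
    assert np.isnan(track.frame["ratio"].iloc[2])


def test_partial_final_window_kept():
    spec = WindowSpec(window_size=10 * MB, step=1 * MB, min_expected=0)
    mm, G = toy_chromosome([25 * MB], ["AA"])
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=25 * MB)
    assert track.frame["start"].iloc[-1] == 24 * MB
    assert track.frame["end"].iloc[-1] == 34 * MB  # extends past the chromosome end
    assert track.frame["n_expected"].iloc[-1] == 1


def test_partition_conserves_missingness_counts(cohort):
    """Summing observed counts over a non-overlapping partition equals
    mapped-minus-missing from the missingness summary."""
    _, mm, G, _ = cohort
    spec = WindowSpec(window_size=10 * MB, step=10 * MB, min_expected=0)
    for sample in ("SubL1", "P1"):
        summary = summarize_missingness(G, mm, sample).frame.set_index("chromosome")
        for chrom, length in {"4A": 40 * MB, "4B": 50 * MB, "4D": 30 * MB}.items():
            track = scan_chromosome(G, mm, sample, chrom, spec, chromosome_length=length)
            assert int(track.frame["n_expected"].sum()) == summary.loc[chrom, "n_mapped"]
            assert (
                int(track.frame["n_observed"].sum())
                == summary.loc[chrom, "n_mapped"] - summary.loc[chrom, "n_missing"]
            )


def test_chromosome_length_below_max_position_rejected():
    mm, G = toy_chromosome([25 * MB], ["AA"])
    with pytest.raises(InputError):
        scan_chromosome(G, mm, "S", "4B", WindowSpec(), chromosome_length=20 * MB)


def test_parents_called_restricts_expected_universe():
    mm, _ = toy_chromosome([1, 2, 3], ["AA", "AA", "AA"])
    G = GenotypeMatrix(
        pd.DataFrame(
            {"S": ["AA", "AA", "NC"], "P": ["AA", "NC", "AA"]},
            index=pd.Index(["m0", "m1", "m2"], name="marker"),
        )
    )
    spec = WindowSpec(window_size=10, step=10, min_expected=0)
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=10, parents=["P"])
    assert list(track.frame["n_expected"]) == [2]  # m1 dropped: parent NC
    assert list(track.frame["n_observed"]) == [1]  # m2 expected but NC in S


def test_coverage_fraction_extremes_and_undefined():
    frame = pd.DataFrame(
        {"start": [0, 1, 2], "end": [10, 11, 12], "n_expected": [9, 9, 9],
         "n_observed": [9, 9, 9], "ratio": [1.0, 1.0, 1.0]}
    )
    track = WindowRatioTrack("4B", frame)
    assert coverage_fraction(track, 0.7) == 0.0
    frame2 = frame.assign(ratio=[0.4, 0.4, 0.4])
    assert coverage_fraction(WindowRatioTrack("4B", frame2), 0.7) == 1.0
    empty = frame.assign(ratio=[np.nan] * 3)
    with pytest.raises(UndefinedResultError):
        coverage_fraction(WindowRatioTrack("4B", empty), 0.7)


def test_bed_round_trip_and_overlap_preserved(tmp_path):
    rng = np.random.default_rng(1)
    positions = sorted(int(p) for p in rng.integers(1, 30 * MB, size=300))
    calls = [("NC" if rng.random() < 0.5 else "BB") for _ in positions]
    mm, G = toy_chromosome(positions, calls)
    track = scan_chromosome(G, mm, "S", "4B", WindowSpec(), chromosome_length=30 * MB)
    bed = tmp_path / "track.bed"
    export_track(track, bed)
    lines = bed.read_text().splitlines()
    assert len(lines) == len(track.frame)
    # sliding windows overlap and are serialized unmerged
    s0, e0 = lines[0].split("\t")[1:3]
    s1, e1 = lines[1].split("\t")[1:3]
    assert int(s1) < int(e0)
    back = read_track_bed(bed)
    np.testing.assert_allclose(
        back.frame["ratio"].to_numpy(),
        np.round(track.frame["ratio"].to_numpy(), 6),
        atol=1e-9,
        equal_nan=True,
    )
    assert back.chromosome == "4B"


def test_three_window_toy_bed(tmp_path):
    mm, G = toy_chromosome([1, 11, 21], ["AA", "AA", "NC"])
    spec = WindowSpec(window_size=10, step=10, min_expected=1)
    track = scan_chromosome(G, mm, "S", "4B", spec, chromosome_length=30)
    bed = tmp_path / "toy.bed"
    export_track(track, bed)
    assert bed.read_text() == (
        "4B\t0\t10\t1.000000\n4B\t10\t20\t1.000000\n4B\t20\t30\t0.000000\n"
    )


def test_plot_written(tmp_path, cohort):
    _, mm, G, _ = cohort
    track = scan_chromosome(G, mm, "SubL1", "4B", WindowSpec(), chromosome_length=50 * MB)
    png = tmp_path / "track.png"
    export_track(track, tmp_path / "t.bed", plot_path=png)
    assert png.stat().st_size > 0
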