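"""Seeded parameter-recovery and specificity experiments.

These run the full simulate → summarize → scan → call pipeline over many
independent synthetic cohorts and tally how often the caller recovers the
true substituted chromosome (sensitivity) and how often it calls a
substitution in a cohort containing none (specificity).  Every cohort is
deterministic given its seed.
"""

from __future__ import annotations

from .caller import CallerParams, call_cohort
from .simulate import (
    SampleSpec,
    SimulationConfig,
    WHEAT_CHROMOSOME_LENGTHS,
    simulate_genotypes,
    simulate_marker_map,
)


def _cohort_config(sample: SampleSpec, n_markers: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        chromosome_lengths=dict(WHEAT_CHROMOSOME_LENGTHS),
        n_markers=n_markers,
        samples=(sample,),
        divergent_chromosomes={"2D": 0.079, "7B": 0.083},
        seed=seed,
    )


def substitution_recovery(
    n_cohorts: int,
    base_seed: int = 0,
    n_markers: int = 21_000,
    params: CallerParams = CallerParams(),
) -> dict:
    """Simulate one substitution line per cohort (the substituted
    chromosome cycles through all 21) and count correct calls."""
    chroms = list(WHEAT_CHROMOSOME_LENGTHS)
    recovered = 0
    for i in range(n_cohorts):
        chrom = chroms[i % len(chroms)]
        config = _cohort_config(
            SampleSpec("SubL", "substitution_line", chrom), n_markers, base_seed + i
        )
        marker_map = simulate_marker_map(config)
        genotypes, _ = simulate_genotypes(marker_map, config)
        call = call_cohort(
            genotypes,
            marker_map,
            ["SubL"],
            params,
            chromosome_lengths=config.chromosome_lengths,
        )[0]
        if call.verdict == "substitution" and call.called_chromosome == chrom:
            recovered += 1
    return {"n_cohorts": n_cohorts, "n_recovered": recovered}


def null_false_calls(
    n_cohorts: int,
    base_seed: int = 0,
    n_markers: int = 21_000,
    params: CallerParams = CallerParams(),
) -> dict:
    """Simulate alien-free derivatives and count spurious substitution
    (or ambiguous) verdicts."""
    false_calls = 0
    for i in range(n_cohorts):
        config = _cohort_config(
            SampleSpec("N", "no_alien_derivative"), n_markers, base_seed + i
        )
        marker_map = simulate_marker_map(config)
        genotypes, _ = simulate_genotypes(marker_map, config)
        call = call_cohort(
            genotypes,
            marker_map,
            ["N"],
            params,
            chromosome_lengths=config.chromosome_lengths,
        )[0]
        if call.verdict != "no_substitution":
            false_calls += 1
    return {"n_cohorts": n_cohorts, "n_false_calls": false_calls}
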