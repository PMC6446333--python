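"""Independent brute-force oracles and frozen reference data for the tests.

Every oracle here is a deliberately naive re-implementation (python loops,
position-by-position) kept free of any code path from the package itself.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def naive_find_hits(query: str, reference: dict[str, str], max_mismatch: int):
    """Position-by-position ungapped scan, both strands.

    Returns a sorted list of (chrom, start_1based, strand, mismatches).
    Only A/C/G/T match themselves; anything else (N, ambiguity codes)
    never matches.
    """
    acgt = set("ACGT")
    out = []
    for strand, q in (("+", query.upper()), ("-", revcomp(query))):
        m = len(q)
        for chrom, ref in reference.items():
            ref = ref.upper()
            for i in range(len(ref) - m + 1):
                mm = 0
                for a, b in zip(ref[i : i + m], q):
                    if a != b or a not in acgt or b not in acgt:
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    out.append((chrom, i + 1, strand, mm))
    out.sort(key=lambda h: (h[3], h[0], h[1], h[2]))
    return out


def naive_window_counts(positions, calls, starts, window_size):
    """Per-window (n_expected, n_observed) by looping over every marker.

    Membership rule: a 1-based position p is in [start, start+window)
    iff start < p <= start + window_size.
    """
    expected, observed = [], []
    for s in starts:
        e = o = 0
        for p, c in zip(positions, calls):
            if s < p <= s + window_size:
                e += 1
                if c != "NC":
                    o += 1
        expected.append(e)
        observed.append(o)
    return expected, observed


def naive_shared_filter(markers, calls_by_sample, samples):
    """Loop-over-markers version of the shared homozygous-allele filter.

    markers: list of marker ids (already restricted to the chromosome);
    calls_by_sample: {sample: {marker: call}}.
    Returns (included marker ids, {reason: count}).
    """
    included = []
    reasons = {"missing_in_some": 0, "heterozygous_in_some": 0, "allele_discordant": 0}
    for marker in markers:
        calls = [calls_by_sample[s][marker] for s in samples]
        if any(c == "NC" for c in calls):
            reasons["missing_in_some"] += 1
        elif any(c == "AB" for c in calls):
            reasons["heterozygous_in_some"] += 1
        elif len(set(calls)) > 1:
            reasons["allele_discordant"] += 1
        else:
            included.append(marker)
    return included, reasons


def mutate_one_base(seq: str, rng: np.random.Generator) -> str:
    """Substitute exactly one base for a different one."""
    i = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGT" if b != seq[i]]
    return seq[:i] + alternatives[int(rng.integers(3))] + seq[i + 1 :]


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Published per-chromosome missing-SNP counts for the three 4M^g(4B)
# substitution lines: {chrom: (n_mapped, [(missing, ratio_str), ...])} with
# one (missing, ratio) pair per line L1, L2, L3.
TABLE1 = {
    "1A": (2632, [(35, "1.3%"), (28, "1.1%"), (26, "1.0%")]),
    "1B": (2630, [(27, "1.0%"), (36, "1.4%"), (27, "1.0%")]),
    "1D": (2495, [(19, "0.8%"), (24, "1.0%"), (21, "0.8%")]),
    "2A": (2622, [(14, "0.5%"), (18, "0.7%"), (20, "0.8%")]),
    "2B": (2578, [(33, "1.3%"), (31, "1.2%"), (45, "1.7%")]),
    "2D": (2590, [(204, "7.9%"), (207, "8.0%"), (205, "7.9%")]),
    "3A": (2194, [(31, "1.4%"), (24, "1.1%"), (32, "1.5%")]),
    "3B": (2629, [(32, "1.2%"), (34, "1.3%"), (46, "1.7%")]),
    "3D": (2072, [(17, "0.8%"), (21, "1.0%"), (23, "1.1%")]),
    "4A": (2573, [(34, "1.3%"), (35, "1.4%"), (41, "1.6%")]),
    "4B": (2601, [(1535, "59.0%"), (1560, "60.0%"), (1575, "60.6%")]),
    "4D": (1087, [(28, "2.6%"), (36, "3.3%"), (30, "2.8%")]),
    "5A": (2633, [(37, "1.4%"), (53, "2.0%"), (44, "1.7%")]),
    "5B": (2622, [(39, "1.5%"), (50, "1.9%"), (64, "2.4%")]),
    "5D": (2142, [(33, "1.5%"), (40, "1.9%"), (48, "2.2%")]),
    "6A": (2623, [(40, "1.5%"), (49, "1.9%"), (40, "1.5%")]),
    "6B": (2601, [(94, "3.6%"), (107, "4.1%"), (91, "3.5%")]),
    "6D": (2067, [(30, "1.5%"), (30, "1.5%"), (24, "1.2%")]),
    "7A": (2601, [(28, "1.1%"), (42, "1.6%"), (41, "1.6%")]),
    "7B": (2542, [(212, "8.3%"), (219, "8.6%"), (198, "7.8%")]),
    "7D": (2625, [(23, "0.9%"), (23, "0.9%"), (23, "0.9%")]),
}
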