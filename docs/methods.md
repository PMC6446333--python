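# Methods

## The detection problem

A wheat SNP array genotypes by hybridizing probes designed against wheat
target sequences.  In a derivative of a wheat × wild-relative cross, three
genotypic classes matter here:

* **euploid wheat background** (parents, alien-free derivatives, and —
  importantly — *addition* lines, which keep all 42 wheat chromosomes):
  nearly every mapped marker calls; a marker drops out only at a small
  background rate;
* **alien donor**: only the markers whose probes cross-hybridize with some
  sequence in the alien genome call at all;
* **substitution line**: one wheat chromosome pair is replaced by its alien
  homoeologous pair.  Markers on that chromosome lose their wheat target;
  they call only if the probe also reads the alien homoeolog.

Chip missingness therefore carries a clean signature of a whole-chromosome
substitution — one chromosome with a missing-call ratio an order of
magnitude above background, depressed uniformly from end to end — and no
signature at all of an addition (which is why addition lines are modelled
as euploid wheat and are explicitly outside the caller's reach).

## Probe mapping

Flanking sequences (35–71 nt) are placed by exhaustive ungapped search on
both strands, allowing at most `max_mismatch` (default 1) mismatches.  A
one-base allowance cannot span an indel, so full alignment machinery is
unnecessary; the implementation is a vectorized sliding comparison that is
provably equivalent to a position-by-position scan (and is tested against
one).  Conventions:

* `N` or any ambiguity code, in query or reference, never matches — a
  conservative choice that can only demote a placement;
* hits are scored `matches·match − mismatches·penalty` (+1/−2 by default)
  and gated at expect value `E = K·m·n·e^(−λS) ≤ 10⁻¹⁰` with λ = 1.28,
  K = 0.46, the standard ungapped parameters for +1/−2 nucleotide scoring;
  m is the query length and n the total reference length.  The E-value is a
  pass/fail gate only, so the screen is insensitive to the exact (λ, K)
  within reason; both are configuration;
* a marker is placed only at a **unique best** hit (strictly fewest
  mismatches among gate-passing hits).  Ties are rejected as `ambiguous`
  rather than multiply placed, so every placed marker contributes to
  exactly one chromosome's denominator.  Rejections are reported with
  reasons (`no_hit`, `evalue_fail`, `ambiguous`), never silently dropped.
* positions are recorded 1-based on the forward strand (the leftmost
  reference base of the hit, for either strand).

A reverse-complement palindromic query matching a site is reported once per
strand; such probes are array design flaws and end up rejected as ambiguous
under the unique-best policy.

## Missingness summaries

For each sample and chromosome: `n_mapped` (placed markers present in the
call table), `n_missing` (those with no call), and their ratio.  A
heterozygous call is a *present* call — missingness is about hybridization,
not zygosity; zygosity matters only in the shared-marker filter.  Markers
placed on the reference but absent from the call table are counted into a
discrepancy list and excluded from denominators.  The donor
cross-hybridization rate is computed over **all** markers, mapped or not,
because it describes the array, not the reference.

Ratios are rendered as one-decimal percentages using exact decimal
arithmetic with round-half-even.  This rendering reproduces, from the
printed count pairs, every ratio cell of the published per-chromosome
missing-SNP table for the three substitution lines (all 63 cells are
asserted in the acceptance suite, e.g. 1535/2601 → 59.0 %, 204/2590 →
7.9 %, 29 537/51 159 → 57.7 %).

## Window scan

Windows of `window_size` (default 10 Mb) start at every multiple of `step`
(default 1 Mb) below the chromosome length; the final partial windows are
kept.  Coordinates are 0-based half-open; marker positions are 1-based; a
marker at position *p* belongs to `[start, start+size)` iff
`start < p ≤ start+size` — one centralized rule, so an interior marker is
counted in exactly `window_size/step` windows and a partition
(`step = window_size`) conserves the missingness totals exactly (both are
tested properties).  Windows with fewer than `min_expected` (default 5)
mapped markers get an undefined ratio rather than an unstable one; 0/0
never occurs.

"Expected" defaults to *all mapped markers in the window*.  For real data
where the parents themselves fail to call part of the array, the
alternative `parents=[...]` restricts the expected universe to markers
called in every listed parent; the default was chosen because the
simulator's parents call ~99 % of the array, making the two readings
nearly identical there.

`coverage_fraction(track, t)` is the fraction of defined windows with
ratio ≤ *t* — the operational version of "the loss covers the whole
chromosome".

## Caller

The candidate is the chromosome with the maximum missing ratio.  Three
gates, all configurable and echoed into every call record:

| gate | default | why |
|---|---|---|
| absolute missing ratio | ≥ 0.40 | observed substitutions sit near 0.60; divergent-background chromosomes near 0.08 |
| fold over background | ≥ 5× median of the other chromosomes | the median is robust to a couple of elevated divergent chromosomes; observed folds are ~7–45× |
| depressed-window coverage | ≥ 0.8 of defined windows ≤ 0.7 | separates whole-chromosome events from segmental introgressions |

Verdicts: `substitution` (all gates pass), `ambiguous` (ratio gates pass
but coverage fails — a segmental suspect flagged for human review — or the
maximum ratio is tied), else `no_substitution`.  The published screen
states no numeric decision rule ("greatly exceeded"); these thresholds are
this package's formalization, chosen to sit well inside the observed
margin between ~0.59–0.61 substituted and ≤ 0.086 background ratios, and
they are deliberately surfaced in every report rather than hidden.

A multi-chromosome substitution would surface as `ambiguous`, never as two
calls: double substitutions are biologically possible but outside this
screen's evidence model.

## Shared-marker filter

On the substituted chromosome, a marker is *shared* when its call is
homozygous (`AA`/`BB`) and identical across every substitution line **and**
the alien donor.  "Same homozygous allele in all samples" is the strict
reading — merely being homozygous in each sample separately would admit
discordant probes.  `AB` and `NC` are the only unusable states; exclusion
reasons are tallied with fixed precedence `missing > heterozygous >
discordant` so reason counts are deterministic.  A non-overlapping window
report flags any window with zero shared markers, the quick
whole-chromosome-coverage check.

## Synthetic cohorts

Per marker (drawn once, shared by all samples): a uniform genome position,
a wheat allele (AA/BB at ½), a **cross-hybridization** flag at
`p_cross_hybridize` (default 0.577 — the observed fraction of array
features calling in the donor), and a **retained** flag — does the probe
read the alien *homoeolog* specifically — drawn at
`p_retained_on_substituted` (default 0.693) *conditional on*
cross-hybridizing.  Alien-derived calls are homozygous; the alien allele
equals the wheat allele with probability `p_alien_allele_matches_wheat`
(default 0.5).  Per sample: wheat-background calls drop out at
`p_background_missing` (default 0.012, the level of the published
background rows) or at an elevated per-chromosome rate for designated
divergent chromosomes (default 0.079/0.083 for 2D/7B, mirroring the two
elevated rows of the published table); non-missing wheat calls are `AB`
with probability 0.01.  A substitution line's markers on the substituted
chromosome call iff retained and not background-dropped, showing the alien
allele; everywhere else, and for addition lines and alien-free
derivatives, behaviour is euploid wheat.

Why conditional retention at 0.693 rather than a marginal 0.40: presence
in a substitution line requires the probe to read the alien homoeolog,
which is a *subset* of reading the alien genome anywhere.  With the
genome-wide cross-hybridization rate at 0.577, conditional retention
0.693 gives a marginal present fraction 0.577 × 0.693 ≈ 0.40 and hence a
substituted-chromosome missing ratio 1 − 0.577·0.693·(1 − 0.012) ≈ 0.605 —
both matching the observed ~40 % present / ~60 % missing.  Modelling the
two draws as independent marginals (0.577 × 0.40) would instead imply 77 %
missing, contradicting the rates the defaults are meant to encode.

Because the retained flags are shared across the substitution lines (the
same physical alien chromosome is interrogated in all of them), the three
lines' substituted-chromosome missing ratios co-fluctuate: the per-cohort
ratio carries a shared binomial component of SD ≈ 1 % at ~2,500 markers on
top of each line's own drop-out noise.  Single-cohort values in the 59–63 %
range are therefore normal at the defaults.

What the simulator does **not** emulate: raw intensities and cluster
geometry, genuine heterozygosity structure (AB is a scalar rate),
segmental introgressions, linkage between markers, and realistic
allele-sharing between homoeologs — the shared-marker *count* in synthetic
cohorts (~900 of ~2,500 on the substituted chromosome) reflects only the
retention/drop-out model, not the far smaller concordant set a real
homoeolog pair yields.  Passing tests demonstrate the pipeline's
correctness and decision behaviour under this model, not array chemistry.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer via `SeedSequence(seed, spawn_key)`; identical
  (config, seed) gives byte-identical TSV/BED/JSON outputs.
* Oracle tests compare the vectorized scans against deliberately naive
  python re-implementations: hit search on a 200 kb two-chromosome
  reference with planted exact and one-mismatch 50-mers, the window
  recount on a 10,000-marker chromosome, and the shared filter on a
  simulated cohort.  These sizes keep the naive oracles honest (pure
  loops) while the whole suite runs in under a minute.
* Recovery/specificity experiments use 21 chromosomes at realistic lengths
  with 21,000 markers (~1,000 per chromosome) per cohort: 100 seeded
  substitution cohorts (the true chromosome cycling through all 21) must
  be recovered in ≥ 95, and 100 null cohorts must yield zero substitution
  or ambiguous calls.  At the defaults the observed recovery is 100/100
  and false calls 0/100; the margin is structural (0.60 vs a 0.40 gate is
  ~20 binomial SDs at 1,000 markers).
* The acceptance script simulates one full 51,159-marker cohort and runs
  50 + 50 recovery/null cohorts, completing in well under a minute.

## Known limitations

* The caller sees only whole-chromosome hybridization loss: additions,
  telosomes and translocations need cytology or other assays.
* Real chips have markers that fail to map or map ambiguously; the
  pipeline reports these but the simulator does not generate them.
* Thresholds were set against a single published substitution family
  (~60 % missing, ≤ 8.6 % background); screens of more diverged donors,
  where cross-hybridization is lower and missing ratios higher, may
  warrant a higher `min_missing_ratio`.
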