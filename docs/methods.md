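# Methods

## Coordinates and conventions

All coordinates are 0-based, half-open (BED-compatible). Integration sites
are single-base coordinates: the chromosomal base adjacent to the viral
part of the junction read (the breakpoint), not a segment midpoint — the
biology of interest is where the fusion happened, and hotspot clusters are
described at base-pair resolution. Sequences are handled case-insensitively
and soft-masked (lowercase) bases are scanned normally; `N` bases in a
genome match no motif character, so assembly gaps can never produce motif
hits.

## Degenerate motif scanning

A motif is an IUPAC string with a mismatch budget k < length. Every window
whose Hamming distance to the pattern is ≤ k is reported, on both strands
by default; minus-strand occurrences are found by scanning the
reverse-complement pattern and are reported in plus-strand coordinates.
Overlapping occurrences are all kept. The scanner is a vectorised
bit-mask comparison (base → 4-bit code, pattern character → allowed-bit
set), O(n·L) per contig — ample for desk scale and still practical at
genome scale; no index structure (suffix array/FM) is built.

Distance queries use the *merged cover*: the union of occurrence intervals
per contig, strand-agnostic (Rep binds double-stranded repeats, and
plus/minus occurrences are pooled). A contig without any occurrence is
*ineligible*: the nearest-motif distance is undefined there, and both the
site sets and the null models are confined to eligible contigs. Sites on
ineligible contigs are dropped with a logged count rather than aborting a
run.

Tandem repeats (`longest_tandem_run`) are counted as maximal runs of
abutting, non-overlapping exact unit matches on the forward strand of the
given sequence — the convention under which the AAVS3 hotspot probe
contains five GAGY units and the AAVS2 probe four. On the AAVS1 probe the
strict run is three; imperfect flanking repeats (as drawn in sequence
alignments of the locus) are deliberately not counted.

## Junction calling

A read is accepted as an integration junction iff all of:

1. its best chromosomal alignment is ≥ `min_long_len` (100 bp) at identity
   ≥ `min_identity` (0.98), **or** contains ≥ `min_short_exact` (25 bp) of
   contiguous exact match;
2. some viral alignment exists;
3. the unassigned read bases between the viral and chromosomal segments
   number ≤ `max_gap` (20 bp);
4. no second chromosomal locus ≥ 1 kb away (or on another contig) also
   satisfies (1) — such repeat-region multimappers are discarded;

and identical fusions (same viral *and* same chromosomal interval) are
counted once. Calls sharing the chromosomal site but differing viral parts
are retained separately. Identity is matches/(matches+mismatches) within
the aligned span; whether query insertions should count against identity is
a dialect question for gapped aligners, and this definition is the package's
choice.

Two details deserve note:

* **Contiguous-exact criterion on PSL input.** PSL records carry the total
  mismatch count but not mismatch positions. When the record was produced
  by the package's own aligner the true longest exact run is stored; for
  plain PSL the criterion uses a *guaranteed lower bound* — the largest run
  that must exist under an adversarial placement of the known mismatches
  across the gap-free blocks (computed greedily). The bound is conservative:
  a short match is accepted only when the 25 bp run provably exists.
* **Microhomology.** Viral and chromosomal read segments may overlap by up
  to 5 bp (junction microhomology is common in end-joining products);
  larger overlaps are rejected. The rejection-reason vocabulary has no
  dedicated code for oversized overlap, so it is reported as
  `gap_too_long` (a junction-geometry failure). A read with *no*
  chromosomal alignment at all (e.g. rearranged pure-virus molecules)
  reports `short_human`.

The bundled aligner is an exact-seed (k ≥ 11), ungapped-extension local
aligner: seed hits are grouped by diagonal and each diagonal is extended to
its maximal-scoring run (+1 match / −3 mismatch, Kadane). It exists so
synthetic tests need no external tool; it does not attempt gapped or
spliced alignment and is not a BLAT replacement.

## Distance statistics and null models

For a site set, the observed statistic is the mean distance x̄ to the
nearest covered motif base (0 inside an occurrence; otherwise distance to
the nearer end of the closed covered interval — measuring to the motif
edge, the natural choice when occurrences have width).

**Exact uniform null.** Under "integration is equally likely at every
position", the null mean μ and SD σ of the nearest-distance are computed in
closed form: every maximal uncovered run between merged cover intervals
contributes a tent (or one-sided ramp at contig edges) of integer
distances, whose Σd and Σd² are arithmetic series accumulated in exact
integer arithmetic; covered bases contribute zeros. μ = Σd/N and
σ² = Σd²/N − μ² over all N positions of eligible contigs. Population
(divide-by-N) SD is used for null models — they describe a complete
distribution — while observed samples display the n−1 sample SD.

**Restriction-matched controls.** Junction retrieval requires a
restriction cut near the provirus, so a non-uniform cut-site landscape
could bias distances. For each observed site, its distance d to the
closest cut of the retrieval enzyme is preserved: each of m = 1000 controls
is placed at a uniformly chosen cut (genome-wide, cut-count-weighted)
± d with random sign, resampling placements that leave the contig or land
on motif-ineligible contigs. Cut coordinates are the blunt-cut centres of
the 6 bp palindromes (PvuII CAG^CTG, EcoRV GAT^ATC, DraI TTT^AAA; offset
+3). The pooled controls' μ, σ enter the same Z-test as the exact null;
whether matched controls should instead yield an empirical p-value is
underdetermined, and the pooled-moments route was chosen for symmetry
across background kinds.

**Tests.** z = (x̄ − μ)/(σ/√n); the scientific hypothesis is directional
(sites *closer* than background), so the one-sided lower-tail p is the
headline number, with the two-sided p always reported alongside.
Significance tiers: p > 0.05 "n.s.", p < 0.01 "highly significant".
Proximity is claimed only when **every** configured background model
rejects. Comparisons between two site sets (e.g. wild-type virus vs
rep-deficient vector) use Welch's unequal-variance t-test — no
equal-variance justification is available, so the pooled form is avoided.
No multiple-testing correction is applied across the motif panel; the
panel is a family of related hypotheses reported side by side, not a
discovery screen.

## Feature enrichment

Feature classes are merged half-open interval sets; point anchors (TSS,
CpG, peak centres) become symmetric windows (±2 kb for TSS/CpG, 5 kb
total around ChIP peak centres), clipped to contig bounds. Gene strand is
ignored for overlap. The observed fraction k/n of sites inside a feature
is tested against the *realised* fraction p̂ of 100,000 uniform random
control sites (drawn over non-N bases, contigs weighted by usable length)
with a two-tailed exact binomial test using the tail-doubling convention,
p = min(1, 2·min(P(X≤k), P(X≥k))). The minlike ("method of small
p-values") alternative exists but is not the default. Whether real
analyses should exclude assembly gaps from the control draw is a judgment
call; non-N masking is supported and used when a mask is supplied.

## Synthetic data

The generator emulates the structure of a junction-retrieval experiment,
not its noise: i.i.d. background bases at a configurable GC (default 0.41,
human-like), motifs planted at Poisson positions (non-overlapping, with
degenerate characters resolved randomly per instance), an optional
duplicated 2 kb block to create repeat-region multimappers, and a
synthetic 4.7 kb viral reference with inverted-terminal-repeat-like ends
carrying an embedded `GAGCGAGCGAGCGCGC` block (a real viral FASTA can be
supplied instead; none is downloaded).

Integration sites follow a mixture: with probability π a site is placed at
an Exponential(λ)-distributed offset (rounded to bp) to a random side of a
uniformly chosen occurrence, else uniformly. The exponential kernel
reflects the empirical picture of integration clusters within a few bp of
an RBS coexisting with sites tens of kb away; λ is configurable (default
500 bp; π default 0.3; n = 117 sites on a 5 Mb, four-contig genome with
the planted motif at 1/50 kb — the reference conditions used by the
calibration checks and the acceptance script).

Clean reads are viral-3'-segment + uniform 0–20 bp insert + chromosomal
segment starting at the site (random orientation; lengths 60–200 and
120–400 bp). Up to four read bases immediately adjacent to the chromosomal
segment are mutated whenever they coincide with the genomic continuation,
so a clean read's breakpoint is unambiguous *by construction* — without
this, coincidental 1–4 bp microhomology shifts the recovered coordinate,
which is a property of real data the generator deliberately does not
emulate. Decoy classes (pure rearranged virus, 24 bp chromosomal stubs,
21 bp gaps, exact duplicates, repeat-block reads) are each constructed to
violate exactly one criterion. Every stage draws from its own named
substream of `numpy.random.default_rng([seed, stage])`, so all artifacts
are byte-identical under a fixed config.

What passing on synthetic data does **not** show: robustness to sequencing
error, quality-score handling, concatemeric/rearranged proviral
structures beyond the decoy classes, GC- or repeat-driven alignment
artifacts of real genomes, or the behaviour of the statistics on a real
assembly's motif landscape.

## Calibration behaviour and a known limitation

Under the reference conditions with π = 0 the one-sided Z-test at α = 0.05
rejects in ≈ 4–5% of 1000 replicates (within the binomial band around the
nominal level). Under π = 0.3, λ = 500 bp the measured power at the
p < 0.01 threshold is ≈ 0.82–0.88, which a normal-approximation
calculation confirms is the expected value for these exact conditions: the
null nearest-distance is approximately Exponential with mean ≈ 1/(2ρ) for
occurrence density ρ, giving a rejection threshold of
x̄ < μ − 2.326·σ/√117, while the π = 0.3 mixture shifts the mean by only
0.3·μ — about 0.9 null-SE short of the threshold. Detecting this effect
size at ≥ 90% power would require either n ≈ 160 sites, a larger targeted
fraction, or a relaxed threshold; the defaults stay at the stated study
conditions rather than being adjusted to make the check comfortable.

## Problem sizes

Unit and property tests run on 10–60 kb sequences and 0.2–0.8 Mb genomes;
calibration uses the 5 Mb reference genome with 1000 null and 100
alternative replicates; the acceptance script regenerates everything from
its seed in a few seconds. These sizes were chosen as the smallest at
which the stochastic checks are stable.
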