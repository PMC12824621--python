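# Methods

## The rearrangement model

We model a locus on one homolog of a diploid genome.  The other homolog is
assumed intact throughout ("intact-homolog assumption"): every total copy
number CN observed in depth decomposes as 1 copy from the normal homolog
plus an allele multiplicity `m = CN − 1` on the rearranged one.  This is the
configuration supported by pedigree data for the class of events the
package targets (de novo or single-parent-transmitted gains); biallelic
events (CN < 1 anywhere) are rejected explicitly.

A rearranged allele is a **walk**: an ordered list of (segment,
orientation) steps over a partition of the locus, starting at the left
flank and ending at the right flank, both in forward orientation.  Walk
legality requires

* each segment traversed exactly `m` times;
* consecutive steps joined either by reference continuity or by a junction
  edge, and orientation flips only across inverted junction edges;
* every junction call explained by at least one traversed edge (when a call
  has alternative placements, at least one placement).

Breakend ends are typed `T` (tail: the junction uses the 3′ end of the
flanking material on the reference forward strand) or `H` (head: the 5′
end).  Orientation classes map to BEDPE strand pairs as
`T/T → (−,−)` (tail-to-tail), `H/H → (+,+)` (head-to-head), and mixed
`T/H` pairs to `(+,−)`/`(−,+)` (deletion-like / tandem-dup-like) depending
on position order.

### Why four architectures

For the canonical inverted duplication–triplication evidence — multiplicity
vector (1, 2, 3, 2, 1) over flank / dup / trp / dup / flank, one
tail-to-tail distal junction and one head-to-head proximal junction — the
walk constraints admit exactly four solutions.  Every solution is three
runs, forward–inverted–forward; the four correspond to the four ways of
assigning the two proximal breakends to {inverted-run start, final-run
start} and the two distal breakends to {first-run end, inverted-run end},
i.e. the central inverted run may span the triplicated core alone, core +
proximal dup, core + distal dup, or all three.  All four predict identical
junctions and an identical CN profile (`evidence_roundtrip` verifies this),
which is precisely the ambiguity the enumeration makes explicit.

A conservation property worth recording: because all enumerated walks share
the breakpoint set and multiplicities, the number of junction attachments
at any partition boundary is identical across walks.  Consequently a gene
straddling a shared junction breakend has the same number of intact and
truncated copies in *every* walk — the per-walk `disrupted` flag is
well-defined but cannot differ between evidence-equivalent walks.
Differential gene disruption between solutions only arises when the
solutions place breakpoints differently (e.g. at unresolved positions
inside a repeat), not from the traversal ambiguity itself.

### Canonical form

A linear allele can be read from either end; a walk and its reverse
complement (reversed order, flipped orientations) describe the same
molecule.  Walks are reported in the 5′→3′ reference-forward anchoring and
deduplicated by the lexicographically smaller of the pair, so a structure
and its mirror count once.

## The palindrome and the proximal breakpoint

The generator's reference is `flank | arm1 | spacer | arm2 | dup_left | trp
| dup_right | flank`, with arm2 the reverse complement of arm1 except at
planted divergences.  Arm identity is exact by construction: at identity
`q`, `round((1 − q)·arm_len)` positions mismatch between arm1 and
revcomp(arm2), two of which are the cis-morphism sites (so identity 1.0
with sites requested is a configuration error).

The planted inverted duplication–triplications use a **homology-mediated
proximal junction**: the strand switch occurs between paralogous positions
`p1 ∈ arm1` and `p2 ∈ arm2` (placed midway between the cis-morphism sites),
so the junction is sequence-seamless — which is exactly why such breakpoints
are invisible to short-read mapping and why long-read cis-morphism phase
resolves them.  The resulting total CN profile is

    2 | 3 on [p1, p2) | 4 on [p2, trp_end) | 3 on dup_right | 2

the proximal CN-3 shoulder lies *inside* the palindrome (arm1 tail + spacer
+ arm2 head), and the triplicated core spans the distal part of arm2, the
`dup_left` segment and `trp`.  The distal junction is the visible
tail-to-tail (−/−) junction spanning `dup_right`.  When partitioning real
evidence, a breakend inside an annotated inverted-repeat pair gets its
reflected paralogous placement recorded; placements that reduce to
reference continuity (a tail joined to a head at one boundary — the
seamless case) anchor no extra graph edge, and distinct placements snapping
to one boundary pair are merged.

### Cis-morphism conventions

Each site stores genomic positions in both arms and both alleles expressed
in the arm-1 forward reading frame (the arm-2 allele is the complement of
the reference-forward base at the arm-2 position).  The simulator reports
long-read observations in the same frame: material derived from arm 1 shows
the arm-1 allele and material from arm 2 the arm-2 allele, whatever the
traversal orientation.  A read informative for phasing observes each of the
two sites exactly once; reads spanning a whole palindrome (observing a site
in both arms) are discarded as ambiguous, as are reads carrying a third
allele at a site (treated as sequencing error).

Phasing calls a breakpoint when one chimeric pattern (different arms at the
two sites) is supported by ≥ `min_informative_reads` (default 5 — the
literature case with only four supporting reads was deemed insufficient,
and the default sits just above) and by ≥ `confidence_threshold` (default
0.8) of all chimeric reads.  The reported interval is the open inter-site
interval in arm-1 coordinates; the paralogous arm-2 interval is implied by
the palindrome symmetry.  Insufficient evidence is a no-call result with a
reason string, never an exception.

## Depth model and mosaicism

`haploid_depth` is the mean number of sequenced *fragments per bin* per
haploid copy.  The default 60 represents 36× total short-read coverage at
500 bp bins: 18× per haploid × 500 / 150 bp reads.  A bin over a region
with rearranged-homolog multiplicity `m` in a carrier fraction `f` has mean

    haploid_depth × (2 + f·(m − 1))

— every cell contributes the intact homolog plus either the normal or the
rearranged allele; `f = 1` recovers the constitutional
`haploid_depth × CN`.  Noise is Poisson by default, with an optional
gamma-Poisson (negative binomial) mode for overdispersion stress tests and
a noiseless mode for deterministic round-trip checks.

Segmentation is a Viterbi MAP path over states CN 0–6 (CN 0 uses a small
floor mean of 0.05 haploid units to keep the likelihood finite), uniform
transition penalty ln(10⁴) per state change, ties broken toward the lower
copy number so output is deterministic.  Segments shorter than 3 bins are
absorbed into the neighbor with the closer mean ratio, suppressing
single-bin flickers of the kind mapping-quality patchiness produces over
repeats.  Masked bins (optional) contribute no emission term.  At the
default depth the four breakpoints of the stepped profile are recovered
within ±1 bin in ≥ 95 of 100 seeded replicates; at half that fragment
count the Poisson log-likelihood-ratio random walk makes ±1-bin placement
unreachable at that rate, which fixed the default.

The mosaic fraction estimator inverts the depth ratio of a gained segment:
`f = 2(r − 1)/k` with `k = m − 1` (1 in dup-only shoulders, 2 in the
triplicated core), with a Poisson-propagated standard error
`SE(r) = sqrt(r / (n_bins × diploid_mean))` and a clipped 95% interval.
Ratios below 1 clip to f = 0 with a warning.

## Junction clustering

BEDPE rows sharing chromosome and strand pairs merge when both breakends
lie within `max_cluster_distance` (default 500 bp) of the cluster medians;
calls need `min_support` (default 3) rows.  Rows are sorted before
clustering, making the result permutation-invariant; clustering call
output again is a fixed point at `min_support = 1`.

## Inverted-repeat detection

Exact k-mer seeds (k = 16) between the sequence and its reverse complement
are grouped by anti-diagonal (`i + j + k`, constant across a perfect
inverted repeat), chained, and extended by an X-drop scheme (+1 match, −3
mismatch, drop 20) that pins arm ends at the homology boundary; candidate
arms are filtered by `min_arm`, `max_spacer` and mismatch fraction, and
overlapping candidates resolved longest-first.  Desk-scale sequences
(≪ 1 Mb) need no suffix-array machinery.  Detection output mirrors
coordinates exactly under reverse complement of the input.

## Cohort and expression analytics

Printed 1-based inclusive coordinates convert to internal 0-based half-open
on input and back on output; printed lengths use the inclusive convention
(end − start + 1), which agrees with exclusive arithmetic at the precisions
reported.  The minimal region of overlap is a plain interval intersection
(order-invariant, associative, monotone shrinking), propagating an
`approximate` flag.  Population screening keeps calls ≥ 10 kb overlapping
the target by ≥ 1 bp (permissive by design; configurable) and classifies
copy ratios: DUP in [1.15, 1.75), TRIP ≥ 1.75 — placing constitutional
expectations 1.5 and 2.0 centrally and empirically observed duplication
bands (≈ 1.27–1.56) comfortably inside the DUP band.

Expression analysis is the transparent cohort statistic, not an
autoencoder-controlled outlier model: TPM normalized to a housekeeping gene,
fold change FC = index / mean(cohort) and z-score against the cohort, the
cohort always excluding the index sample (avoids self-contamination at
small n).  Genes with cohort mean < 1 TPM are masked (ratio instability);
genes degenerate after normalization (the housekeeper itself) are skipped.
The naive dosage model FC = CN/2 gives the reference expectation (2.0 for a
constitutional triplication); observed fold changes in real tissues tend to
fall somewhat below it.

## Synthetic-data conditions and their limits

Generator defaults are the study conditions: 20 kb palindrome arms at 99.8%
identity with cis-morphisms 4.2 kb apart, 30/40/30 kb dup/trp/dup segments,
50 kb flanks, 36× coverage in 500 bp bins, ~20 kb long reads with 1%
per-base substitution error, an expression cohort of 100 controls at
cv = 0.1 with a planted FC of 2.0, and 19 planted target-overlapping
duplications (copy ratios ~N(1.5, 0.08) truncated to the duplication
regime) in a 500 000-sample screen.  Arm length is desk-scaled (the real
locus has 33 kb arms inside a 144 kb palindrome); all geometric
relationships are preserved.

What the generator does *not* emulate, and hence what green tests do not
establish about real data: GC and mappability bias in depth (no
low-mapping-quality patchiness over the repeat — real proximal CN steps
inside a palindrome are largely unobservable), alignment and its artifacts
(allele observations are derived from the known haplotype structure, not
re-mapped), indel/chimeric long-read errors, population structure in the
CNV screen, and biological expression covariates that motivate
autoencoder-based outlier control at scale.  Quantities that in the source
study required controlled-access cohorts (large-cohort fold changes and
z-scores, biobank duplication counts, the mosaic parent's measured
fraction) are validated here only against planted synthetic truth.

## Numerical and interface choices

* Internal coordinates 0-based half-open everywhere; BED/BEDPE writers emit
  that convention; HGVS-style printed coordinates converted at the
  boundaries.
* Transition-penalty and tie-break choices make segmentation deterministic;
  enumeration output is sorted lexicographically and deduplicated by
  canonical form, so all list outputs are reproducible bit-for-bit for a
  given seed.
* `max_walks` defaults to 64: realistic fixtures yield ≤ 4 walks; the guard
  raises a truncation error on adversarial inputs rather than hanging.
* Junction-to-CN-step matching tolerance is 2 bins (1 kb at default bin
  size): junction positions, being split-read-precise, are preferred as
  partition boundary representatives.
* Degenerate inputs: empty depth tables, zero baselines, missing/zero
  housekeeping values, cohorts smaller than 3, single-interval overlaps and
  infeasible walk constraints all fail fast with specific messages (or, for
  phasing, return a reasoned no-call).
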