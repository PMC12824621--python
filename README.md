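# duptrp

Reconstruction of palindrome-mediated inverted duplication–triplications
(DUP-TRP/INV-DUP) from sequencing evidence.

Complex copy-number gains in which a triplicated segment is embedded,
usually inverted, within a duplication are a recurrent cause of genomic
disorders — for example the 16p13.3 triplications spanning *ATP6V0C* that
arise next to a large 144 kb palindrome.  Standard callers describe such an
event as a pile of overlapping inversions and duplications, but it involves
just two breakpoint junctions, and several distinct haplotype structures
explain the same short-read data.  `duptrp` is a toolkit for geneticists and
methods developers who want to reason about these events quantitatively:

* **cn_segmentation** — binned read depth → integer total copy-number
  segments (the stepped 2–3–4–3–2 profile) via a Viterbi path with Poisson
  emissions, plus mosaic-fraction estimation `f = 2(r − 1)/k` from
  non-integer copy ratios.
* **junctions** — parsing, clustering and orientation-classing of
  discordant/split read-pair evidence (BEDPE): `(−,−)` tail-to-tail and
  `(+,+)` head-to-head inverted junctions, deletion-like and tandem-dup-like.
* **architecture** — a breakpoint graph over the CN segments (allele
  multiplicity `m = CN − 1` under the intact-homolog assumption) and
  exhaustive enumeration of every haplotype walk consistent with the
  evidence, with per-gene copy counts and disruption flags for each walk.
* **palindrome_phase** — inverted-repeat detection and localization of a
  repeat-internal breakpoint from the phase of two *cis*-morphisms
  (paralog-distinguishing sites) in long reads.
* **cohort / expression** — minimal region of overlap across individuals,
  size summaries, population CNV screening by copy ratio, and
  housekeeping-normalized dosage outlier scores (fold change above the
  cohort mean and cohort z-score).
* **synthetic_data** — a generator that emulates the whole evidence chain
  (reference with palindrome and cis-morphisms, planted architecture, depth,
  junction pairs, long reads, expression cohort, population CNV table) with
  known truth.

## Worked example

Simulate a constitutional inverted duplication–triplication and run the
inference chain (`duptrp --help` lists all commands):

```sh
duptrp simulate --outdir demo --seed 3 --architecture DUPTRP_2
duptrp segment --depth demo/depth.tsv --baseline flank_median --out demo/segments.tsv
```

```
chr16_sim:0-60000       CN=2  r=0.985  bins=120
chr16_sim:60000-82000   CN=3  r=1.480  bins=44
chr16_sim:82000-162000  CN=4  r=1.958  bins=160
chr16_sim:162000-192000 CN=3  r=1.489  bins=60
chr16_sim:192000-242000 CN=2  r=0.988  bins=100
```

The stepped 2–3–4–3–2 profile: copy ratios near 1.5 flag the duplicated
shoulders and near 2.0 the triplicated core.  Cluster the split-read
evidence and enumerate the structures that explain it:

```sh
duptrp junctions --bedpe demo/junction_evidence.bedpe --out demo/calls.bedpe
duptrp enumerate --segments demo/segments.tsv --junctions demo/calls.bedpe \
                 --genes demo/genes.bed --out demo/walks.tsv
```

```
chr16_sim:60008(+) -- chr16_sim:82026(+)    INV_HEAD_HEAD  support=10
chr16_sim:162008(-) -- chr16_sim:191983(-)  INV_TAIL_TAIL  support=10
4 architecture(s) consistent with the evidence:
  walk_1: S0 S1 S2 S3 S2' S1 S2 S3 S4
  walk_2: S0 S1 S2 S3 S2' S1' S2 S3 S4
  walk_3: S0 S1 S2 S3' S2' S1 S2 S3 S4
  walk_4: S0 S1 S2 S3' S2' S1' S2 S3 S4
  walk_1  ATP6V0C  copies=3  disrupted=False
```

Exactly two junctions (one `+/+` proximal, one `−/−` distal) despite the
event being callable as five separate variants, and exactly four canonical
walks (`'` marks an inverted traversal) that differ only in the span of the
central inverted run — yet a gene inside the triplicated segment carries 3
copies on the rearranged allele in *every* solution, so its dosage
interpretation is robust to the ambiguity.

The proximal junction lies inside the near-identical palindrome arms, so its
exact position is invisible to mapping; long reads that span the two
cis-morphism sites resolve it.  Reads drawn across the junction show a
chimeric site pattern and localize the breakpoint to the 4.2 kb inter-site
interval (`duptrp phase --reads obs.tsv --sites demo/sites.tsv`); with only
a handful of chimeric reads the module reports an honest no-call.

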