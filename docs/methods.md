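# Methods

This note documents the models, conventions and design decisions behind
`smmipseq`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic data does and does not emulate.

## Probe architecture and panel design

An smMIP consists of an extension arm (16–30 nt) and a ligation arm
(18–30 nt) that hybridize to the antisense strand of a cDNA, separated by a
fixed 112-nt gap that is filled and ligated. The arms are joined by a
constant 40-nt backbone (a repository constant; the physical backbone is a
reagent whose sequence is not data) carrying an 8-nt UMI adjacent to the
ligation arm. Internally all coordinates are 0-based half-open transcript
coordinates; 1-based numbering appears only in HGVS output.

**Candidate enumeration** slides the 112-nt gap along the transcript at a
configurable stride (default 10 nt; stride 1 for full-coverage tiling).
Arm lengths are chosen per window as the shortest length whose target GC
lies in [0.2, 0.8]; if no length qualifies the minimum length is used and
the score carries the penalty. Only arm minima are dictated by the assay;
maxima, the GC window and the stride are package defaults.

**Scoring** is a transparent product of per-arm penalties: GC outside
[0.2, 0.8] penalized linearly in the excess (factor `1 − 2·excess`),
homopolymer runs ≥ 6 nt penalized linearly in the run length beyond 5
(factor `1 − 0.25·(run−5)`), and any ambiguous base zeroing the score.
This deliberately replaces trained capture-efficiency models with an
auditable heuristic; it is not a re-implementation of any published
predictor.

**Selection** picks `n_per_transcript` (default 5, up to 10) candidates
whose gap midpoints best match an ideal evenly spaced grid across the CDS
(greedy nearest-to-grid; ties by score, then gap start, then id).
Junction-spanning candidates — arms on different exons, which makes
genomic-DNA capture impossible — receive a 10-nt distance credit, and if a
multi-exon transcript ends up without one although a candidate exists, the
best junction candidate replaces the selected probe at its nearest grid
slot: a soft preference, not a hard filter. Full-coverage mode instead
greedily tiles gap intervals until the union covers the whole CDS.
Selection is deterministic for identical inputs. Transcripts with fewer
than five selectable probes, or with uncovered CDS in full-coverage mode,
are reported as under-covered rather than silently shortened.

The shipped `data/metabolic_panel_targets.tsv` lists the 104 metabolic
target transcripts (with 18 flagged for full-CDS tiling) that motivate the
default panel sizes.

## Read simulation

The simulator is first-class code: it is the ground truth against which the
processing pipeline is validated. The sequenced insert (amplicon) dialect
shared between simulator and processor is

```
ext_target(16–30) + gap_fill(112−d) + lig_target(18–30) + UMI(8) + backbone(40) + barcode(8)
```

with read 1 the first 151 nt and read 2 the reverse complement of the last
151 nt. With minimal arms the insert is 202 nt, so mate 1 always covers the
entire gap fill while mate 2 — entering through barcode, backbone, UMI and
ligation arm — covers only its last `95 − lig_len` bases (77 nt at minimal
arms). Per-position mate-coverage masks propagate through the pipeline;
forward/reverse variant support is therefore position-dependent, exactly as
it is in the real read architecture. PCR primer tails (the difference
between the ~200-nt insert and the physical ~266-bp library band) are not
modeled. The sample barcode is placed in-read rather than in an index read
so demultiplexing is testable from FASTQ alone.

Stochastic layers, each reproducible under a fixed seed:

* **Capture-efficiency dispersion.** Per-probe efficiencies are drawn
  log-normally with log-scale σ = 1.5 (default), emulating the large
  probe-to-probe variability seen in practice; molecule counts follow a
  multinomial over abundance × efficiency.
* **UMIs** are uniform random 8-mers per molecule; at 10³–10⁴ molecules per
  probe, collisions against the 4⁸ = 65,536 UMI space are rare but real,
  which is why truth tables record both molecule counts and distinct
  (smMIP, UMI) counts — deduplication can only recover the latter.
* **PCR duplication**: 1 + Poisson(dup_mean) copies per molecule
  (default mean 1).
* **Sequencing errors**: independent substitutions at `error_rate`
  (default 10⁻³) on every emitted base; no indel errors. Qualities are
  constant Phred 30, so quality-weighted consensus tie-breaks are exercised
  but not informative on simulated data.
* **Spiked variants**: SNVs and contiguous deletions of 1–20 nt at set
  allele fractions, drawn per molecule (Bernoulli). Capture arms pin both
  flanks of the gap, so a d-nt deletion shortens the gap fill to 112 − d.

Molecule-level randomness (counts, alleles, UMIs) and PCR/sequencing
randomness run on two independent streams spawned from the plan seed, so
unique-molecule content is exactly invariant under changes to `dup_mean`
and `error_rate` — a property the tests rely on. FASTQ is written with a
fixed gzip timestamp so fixed-seed runs are byte-identical.

What the simulator does **not** emulate: polymerase sequence bias, quality
decay along reads, indel sequencing errors, fragmentation, index hopping,
cross-sample contamination, and transcript-level phenomena (isoforms,
degradation). Tests passing on this generator therefore demonstrate
algorithmic correctness under the stated noise model, not robustness to
every artifact of real libraries.

## Processing

* **Demultiplexing** compares the reverse-complemented first 8 nt of read 2
  against the barcode table with ≤ 1 mismatch (configurable); the table
  must be pairwise separated by more than twice the tolerance or it is
  rejected as ambiguous up front. Unassigned reads are data, not errors.
* **Probe assignment** is positional, not alignment-based: both arm images
  must match at their fixed read offsets within ≤ 1 mismatch each. The
  best total distance wins; equal-distance ties are left unassigned. An
  exact-match dictionary on the 16-nt read-1 prefix provides a fast path;
  reads with prefix errors fall back to a full scan with early-exit
  Hamming distances.
* **Deletion-length inference** slides the mates against each other over
  candidate deletion lengths 0–20 and picks the offset with the fewest
  overlap mismatches (exact for error-free reads; ties resolve to no
  deletion).
* **UMI collapse** groups by exact (smMIP, UMI) match — no directional or
  network clustering — reflecting the simplest faithful reading of
  UMI-based duplicate removal; the grouping function is isolated and
  swappable. No minimum family size is imposed: singleton molecules count.
  Consensus is a per-position majority over all mate observations in the
  family, ties broken by summed base quality, then alphabetically. Within
  a family the gap-fill length is decided by majority; discordant-length
  read pairs (misinferred deletions) are excluded from voting but still
  counted as duplicates.

Under duplication-only noise the resulting count table equals the
simulator's distinct-UMI truth exactly; at error rate 10⁻³ roughly 1 % of
families split on a UMI-read error, slightly inflating unique counts —
visible, documented behavior of exact-match grouping.

## Quantification

FPM_i = c_i / Σc × 10⁶ with the denominator the sample's total *assigned*
unique reads (unassigned reads are excluded; no housekeeping-gene
normalization). Per-transcript aggregation defaults to the mean over all
probes of the transcript, zeros included — a non-performing probe is
evidence, not missingness; median and best (max) are alternatives. TPM
uses the standard length-normalized transform. FPM–TPM concordance is
Pearson r computed by default on log10(x + 0.01); the pseudocount keeps
zero-FPM transcripts in the analysis below the smallest observed non-zero
values, and a raw-scale option exists since the choice of scale is a
convention. Transcripts present on only one side are reported, never
silently dropped; fewer than three shared transcripts is an error.

On the default study conditions (50 transcripts spanning four decades of
log-uniform abundance, 5 probes each, σ = 1.5, 20,000 molecules) the
log-mean-FPM recovers log true abundance with Pearson r ≈ 0.84–0.92
depending on the seed; the fixed-seed property test pins a configuration at
r ≥ 0.9. The dominant noise source is efficiency dispersion averaged over
only five probes, not counting noise.

## Variant calling and annotation

Each unique molecule contributes at most one forward (mate-1) and one
reverse (mate-2) observation per covered position; overlapping probes pool
their observations. VAF is supporting observations over total observations
at the position under this orientation-split convention (so a molecule seen
by both mates contributes two observations — the convention is defined here
explicitly because commercial tools leave their denominator unstated).

Deletion-bearing consensus sequences (length 112 − d) are placed by exact
best-fit search of a contiguous d-nt deletion over the gap window — optimal
alignment was rejected because it fragments multi-base deletions into
ambiguous pieces — and then right-shifted to the 3'-most equivalent
position, per HGVS convention, before calls from different probes are
merged. One contiguous deletion per molecule per gap is assumed;
insertions are not called.

PASS requires VAF ≥ 5 %, total support ≥ 5 unique reads, and both
orientations represented (≥ 1 each); a strict mode requiring ≥ 5 per
orientation is available, since "at least 5 unique reads (forward and
reverse)" admits both readings and reported support values of the form
22 = 11 + 11 are consistent with the total-count reading. Sub-threshold
alleles at VAF ≥ 2.5 % are emitted with failure reasons for audit; weaker
signals are dropped. Because mate 2 cannot reach the first ~35 gap bases,
variants there can never gain reverse support — a structural blind spot of
the read architecture that the caller reports honestly as an orientation
failure rather than masking.

Annotation translates the affected codons under the standard genetic code:
substitutions classify as synonymous (`p.(=)`), missense, nonsense or
stop-lost; deletions of length not divisible by 3 are frameshifts annotated
as `p.Xaa{n}Yaafs*{k}` by translating the shifted sequence (continuing past
the native CDS end if necessary) to the first novel stop, with `fs*?` when
none is found; in-frame deletions get residue-level del/delins notation
(`inframe_deletion`, an extension of the four-way classification).
Positions outside the CDS receive transcript-level `n.` notation and no
classification. The annotator is validated against a brute-force
translate-and-diff oracle on 1,000 random variants.

The VCF export uses transcript-space coordinates (the header says so);
genomic liftover is out of scope.

## The synthetic VHL coding sequence

`data/vhl_cds_synthetic.fa` is a constructed, clearly labelled stand-in
coding sequence (213 codons), engineered so that the canonical worked
example of this assay class — a CG dinucleotide deletion at c.246_247 —
is 3'-unambiguous and produces `p.Val83Argfs*48` (first changed residue
Val83, novel Arg, new stop 48 codons downstream). The annotation engine
computes this consequence from the sequence at run time; the fixture
encodes the *scenario*, not the answer. It is not the RefSeq VHL sequence
and must not be used for real-data annotation.

## Problem sizes

Default test and acceptance workloads — 50 transcripts × 5 probes, 20,000
molecules (~40,000 read pairs), plus a 2,000-molecule variant-recovery run
and 1,000 oracle annotations — were chosen to give stable statistics
(binomial SE of a VAF estimate at 400 molecules ≈ 2.5 %; SE of a Pearson r
at n = 50 ≈ 0.04) while completing in well under a minute per run on one
core.

## Known limitations

* Exact-match UMI grouping slightly over-counts molecules at realistic
  error rates (no UMI-error correction).
* Arm matching is positional; reads from inserts the dialect does not
  describe (adapters, chimeras) are unassigned rather than rescued.
* The capture-efficiency model is a single log-normal draw per probe; real
  efficiency correlates with arm sequence features, which the score only
  heuristically captures.
* Variant detection sensitivity is position-dependent (mate-2 blind spot,
  probe efficiency), so absence of a call is not absence of a variant.
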