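# Methods

This note documents the models and conventions behind `fishid`: what each
stage computes, the parameters that matter, what the synthetic data does
and does not emulate, and the choices made where the design was open.

## Sequences and pairwise identity

Sequences live on the 16-letter IUPAC nucleotide alphabet plus the gap
character. Input is normalized at parse time (upper-cased, RNA `U` → `T`)
because public barcode exports mix conventions. Two codes *match* when
their concrete-base sets intersect (`R` matches `A`, `G`, `R`, `N`, …); a
gap matches nothing, including another gap.

Percent identity between two barcodes is computed from a pairwise
**semi-global** alignment (Biopython's `PairwiseAligner` with an
IUPAC-aware substitution matrix): match +1, mismatch −1, gap −2, terminal
gaps free. Matches are aligned columns whose base sets intersect;
`compared_positions` excludes terminal-overhang columns (a truncated
record is not penalized for being shorter) but counts internal gap
columns as differences. The scores are configurable; the defaults keep
near-full-length barcodes aligned end-to-end, which is the regime the
panel analysis operates in.

Reported percents round half-up to an integer, **capped at 99 for any
non-identical pair**. The cap reflects reporting practice for barcode
homology tables: a pair differing at 3 of 652 positions (99.54%) is
reported as 99%, never as 100%, because 100% is reserved for identity.
Full precision is retained internally.

Known limitation: the original homology figures were read off a multiple
sequence alignment; pairwise semi-global alignment is a stand-in for it.
For substitution-only divergence (the regime of congeneric COI barcodes)
the two agree exactly; with indels the denominators can differ by a few
columns depending on how gap columns are counted.

## Panels, closest relatives, and the tree

A panel maps species to barcode records, split into targets and
congeneric controls (CONs), each CON flagged for geographic co-occurrence
(Great Lakes). Species with multiple records are represented by a
majority-rule per-position consensus (ties become the covering IUPAC
code); pooling records this way keeps intraspecies variation from
contaminating between-species identity. Consensus requires equal-length
records; real multi-record panels should be pre-aligned or trimmed.

Closest-relative ranking sorts CONs by descending integer identity to
the target, ties lexicographic, optionally restricted to co-occurring
CONs (the filter never reorders survivors).

The guide tree is **UPGMA** on `distance = 100 − percent identity`. Both
the metric and the agglomeration method are this package's own choices —
the tree is a deterministic "who is closest" summary, not a phylogenetic
claim: no rate model, no bootstrap. All ties (equal merge distances,
child ordering) resolve lexicographically, so the Newick string is a
pure function of the matrix.

## Candidate specificity scoring

For each candidate primer/probe set (as imported from upstream design
software, with its design rank), each of the three oligos scores 1
against a CON barcode if it has a **zero-mismatch, full-length, ungapped
occurrence on either strand**; degenerate oligo bases match any
compatible template base (hybridization semantics). Scores are summed
over all CON sequences; candidates sort by ascending total, ties broken
by ascending design rank, and the head of the list is the selected set.
Scoring exact occurrences rather than thermodynamics is deliberate: at
qPCR stringency a single mismatch in a 20-mer is typically disruptive,
and the exact-occurrence count is a conservative, auditable proxy.

Mismatch profiling of a chosen assay reports, per oligo, the
**minimum-mismatch ungapped placement** over all template offsets.
Profiling scans both strands for every oligo — templates arrive in
either orientation — and reports the footprint (0-based half-open
plus-strand interval, strand) of the best placement; ties go to the
smallest offset, plus strand first. Footprints are located by scanning,
not by a precomputed alignment, so profiles need no MSA and are exact
for substitution-only divergence.

The screening step that compared two design methodologies by which gave
the lower measured Cq is represented only as its selection rule
(`select_by_cq`, an argmin over user-supplied values): the Cq values are
laboratory measurements, not something this package can compute.

## In-silico PCR

Binding-site search enumerates every ungapped placement of an oligo on
either strand within a mismatch tolerance (default 0). Amplicons pair a
plus-strand forward site with a downstream minus-strand reverse site,
product length = reverse end − forward start, constrained to the design
window (default 70–150 bp, the assay-design product-size bounds). A
prediction is *valid* only when the probe also binds strictly between
the primer footprints — mirroring the chemistry, where reporter
fluorescence requires all three oligos on the same template. Whether a
probe overlapping a primer footprint should count is genuinely
undefined; strict containment was chosen as the conservative contract.
All qualifying products are reported (callers filter); templates are
linear; coordinates are 0-based half-open plus-strand everywhere.

Panel validation runs every species' representative against an assay at
zero tolerance and passes iff the target yields a valid product and no
other species does.

## The species decoder

One well is positive iff all three gates pass:

| gate | default | meaning |
|---|---|---|
| `cq_cutoff` | 25.0 cycles (inclusive) | target species at the standardized 100 ng input amplify below this; cross-reactions sit well above |
| `require_amp_status` | true | the instrument's own true/false amplification verdict; rejects phantom signals carrying spurious Cq values |
| `delta_rn_min` | 0.3 (inclusive) | normalized reporter magnitude over dye background |

Both thresholds are inclusive. The source material is ambiguous on both
edges ("below 25" vs. 25.23 being "slightly above"; "greater than 0.3"
vs. "0.3 or greater"); no observed datum lies exactly on either
boundary, so inclusivity is unobservable in practice and both gates are
configurable.

Replicate wells group by assay. The default `mean` rule averages the Cq
of wells passing the status and ΔRn gates, then thresholds the mean;
`all`/`any` combine per-well verdicts instead. How duplicates were
combined originally is unstated; the mean rule is this package's
default because it is the least sensitive to a single noisy replicate.
A sample is called as the unique positive assay's species, `NONE` with
zero positives, `MULTIPLE` with two or more (mixed-template runs).

`mixed_sample_mode` switches the Cq gate to `mixed_cq_cutoff` (default
30): with multiple species' DNA in one well, two of the eight assays
(smallmouth bass at 28.71, round whitefish at 25.23 mean Cq) drift above
the single-species cutoff, so mixed runs need an adjusted gate. No
specific adjusted value was published; 30 clears both observed means
while staying far below the ≥32.6 cross-reaction band, and it is a
parameter, not a constant.

DNA input (`dna_input_ng`, default 100) is carried as metadata only; the
decoding rules never consult it.

Blinded scoring: accuracy = correct identifications / samples whose true
species is a panel target (reported as percent, or not-applicable when
no target samples exist); the false-positive count is the number of
CON/non-target samples assigned any species. A confusion table (true
species × assay, positives per sample count) accompanies the metrics.

## Cost and time model

Cost tables are itemized components with a per-sample figure and
optionally a per-96-batch figure; totals are exact sums (half-up cent
rounding at display only), and a component without a batch figure
contributes `per_sample × n` to the batch total. Method comparison ranks
by per-sample total, using a table's *printed* total when one is
attached: the published barcoding totals ($18.79 per sample, $1,319 per
96) do not equal the sum of their own published components ($16.82,
$1,327.74), and whether a component is missing or the arithmetic
slipped is unknowable — so the tables store both figures and every
report flags the disagreement rather than silently picking one. Time
estimates are step-wise (min, max) hour sums: 6–7 h for a 96-sample
qPCR batch, 10–12 h for barcoding, 8–16 h for morphological work.

## Synthetic data

The generators make the pipeline testable offline; their defaults encode
the study conditions the analyses assume.

**Panels.** An ancestral sequence (uniform random A/C/G/T, default
652 bp — the barcode length) carries every planted assay's exact
footprints: forward oligo verbatim, reverse complement of the reverse
oligo, probe verbatim, at spacings that reproduce the assay's expected
amplicon size. Each species then receives an exact number of
substitutions at distinct positions **outside** all footprints, plus an
explicit per-oligo mismatch count **inside** the footprints of each
assay that lists it. Identity targets and footprint mismatch counts are
therefore independently controllable and exactly recoverable — 7
substitutions in 652 bp is 645/652 = 99% by construction. Substitutions
only; no indels, no transition/transversion bias, no rate heterogeneity
along the barcode. Real barcode panels violate all three, which is why
the alignment layer exists; passing the planted-panel tests shows the
scanning and counting machinery is exact, not that real COI divergence
is uniform.

The full validation panel (8 targets + 15 CONs, all eight assays
planted) uses a 1600-bp synthetic reference region so that eight assays'
footprints fit side by side without overlap — the real assays tile an
actual 652-bp barcode, where footprints of different species' assays may
overlap; overlap handling is not needed for the synthetic panel and is
not claimed. Its per-CON footprint mismatches follow the published
in-silico findings (closest whitefish/sculpin relatives at 1–2 total
differences concentrated on reverse primer and probe, Great Lakes
whitefish CONs at 3–5, largemouth bass at 5, everything else ≥6, with
non-target species in the 10–19 band).

**qPCR runs.** Each (sample species, assay) pair has a Cq mean and SEM
from the packaged single-plex statistics table; detectable wells draw
`Cq ~ Normal(mean, noise_scale × SEM)` clipped to (0, 40] cycles (the
40-cycle run length), with true amplification status and ΔRn 1.0;
undetectable pairs emit "Undetermined" with failing status and ΔRn
0.05. The SEM-as-per-replicate-SD simplification is deliberate and
conservative for the accuracy claim: the published SEMs already divide
by √n, so per-replicate spread is understated at `noise_scale = 1`, but
the decision margin (32.61 vs. 25.0 at the closest) is ~22 SEMs wide —
no plausible noise model bridges it. ΔRn magnitudes for positive wells
were never published; 1.0 and 0.05 are invented defaults on either side
of the 0.3 gate.

**Blinded design.** The packaged design lists each sample group once per
probe set (115 samples: 69 targets, 46 controls); each sample is assayed
in duplicate against its set's four multiplexed assays, matching the
plate layout such a trial uses. One published inconsistency: the
spottail-shiner CON groups are listed individually as 16 samples but
summarized elsewhere as 14; the design uses the individual groups.

All generators are bit-reproducible under a fixed seed.

## Problem sizes

The shipped analyses are desk-scale by nature: 920-well simulated runs,
≤23-species panels, 1600-bp templates. The full test suite runs in a few
seconds; the acceptance script in well under a minute.
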