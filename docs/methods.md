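# Methods

This package models the laboratory and computational pipeline used to
screen for, and genotype, expansions of the pentanucleotide short tandem
repeat in intron 2 of *RFC1* (chr4:39348425–39348485, GRCh38). Biallelic
expansions of particular motifs at this locus — pure AAGGG, pure ACAGG,
and the complex "Māori" configuration (AAAGG)₁₅–₂₅(AAGGG)ₑₓₚ(AAAGG)₁₀ —
cause CANVAS; the reference allele is (AAAAG)₁₁ and several other motifs
are benign or of undetermined significance. Every stage operates on a
shared structural vocabulary: a **motif** is a 5- or 6-base unit
identified by its lexicographically minimal rotation (plus strand only;
reverse complements are not merged), and an **allele structure** is an
ordered 5′→3′ list of (motif, copy-count) blocks plus **interruptions**,
operationally defined as 1–9 consecutive units of a foreign motif.

## Synthetic data model

No sequencing data for this locus is publicly deposited, so all inputs
are simulated. The generator's defaults encode the screened study
conditions:

* **Cohort** — 242 samples: 37 biallelic-pathogenic (30 biallelic AAGGG,
  2 biallelic Māori, 2 Māori/AAGGG, 2 biallelic ACAGG, 1 ACAGG/AAGGG),
  45 biallelic non-pathogenic of which 44 carry complex alleles, and 160
  samples with at least one reference-range (8–14 unit) allele. Phenotype
  subgroups (105 ataxia / 50 neuropathy / 45 ataxia+neuropathy /
  42 suspected CANVAS) are assigned independently of genotype class by a
  seeded shuffle, because no joint cross-tabulation is published.
* **Allele sizes** — pathogenic AAGGG 400–1000 units and ACAGG 600–900
  units (pathogenic expansions often exceed 1000 units); benign AAAAG
  60–200 and AAAGG 60–150 units (matching the reported benign range and
  exceeding the 50-unit amplification cap so flanking PCR yields no
  product); Māori AAGGG blocks 300–700 units.
* **Complex samples** cycle through the three consensus genotypes
  recovered by targeted long-read sequencing of patient samples HP220149,
  HP220160 and HP220123 — (AAAAG)₁₂(AAGAC)₂₅₈ / (AAAGG)₁₂(AAAGGG)₃₆(AAGGG)₁₂,
  (AAGGG)₄₀₀ / (AAAGG)₁₂(AAAGGG)₄₆(AAGGG)₁₂, and (AAAAG)₁₂₅ /
  (AAGGG)₁₀₀(AGGGG)₃₀ — with blocks of ≥30 units jittered ±10% per
  sample. Only approximate totals are reported for these alleles; the
  small flanking blocks are fixed at 12 units, comfortably above the
  10-unit block threshold, so that block recovery measures the method
  rather than threshold luck. The full two-allele pairings are kept
  intact: a complex allele paired with a long pure ladder can be
  genuinely invisible to RP-PCR (the partner's ladder masks the gap), and
  the reported patients carry the paired configurations.
* **Reads** — long reads span flank + tract + flank by construction
  (targeted-capture assumption) with independent per-base substitution
  0.02 / insertion 0.03 / deletion 0.04 (nanopore-like; no published
  rates exist for this assay, and the indel-heavy profile deliberately
  stresses the G-rich motif ambiguity). Short reads (150 bp, default 40–50×)
  are uniform over each haplotype with an Illumina-like error model
  (substitutions 0.001, no indels). Flanks are 1000 bp of fixed
  pseudo-random sequence (no mononucleotide run ≥4) generated from a
  locus seed; the true amplicon flanks are not published.

What the generator does **not** emulate: PCR stutter and chimeras,
capture/coverage bias, basecaller-correlated (homopolymer) error, strand
effects, somatic instability, and real flank sequence. Passing tests
therefore demonstrate the pipeline's internal consistency and its noise
tolerance under this error model — not performance on real traces or real
nanopore reads.

## Assay models

**Flanking PCR.** Product length = 300 bp + tract length; alleles above
50 total units yield no product. The 300 bp constant is the unique value
consistent with both printed endpoints of the normal window (340 bp ≈ 8
units, 370 bp ≈ 14 units). A sample is *excluded* if any peak falls in
340–370 bp; an empty trace is *suspected biallelic*; peaks only outside
the window flag an amplifiable intermediate allele (15–50 units) and are
treated as suspected-with-warning. The 50-unit cap is an operational
choice — the boundary between "amplifiable" and "no product" is not
published.

**RP-PCR.** The repeat primer anneals from the 5′ flank; unit *i* of an
allele produces a peak at anchor + cumulative bp of units 1..*i* when
that unit matches the assay motif up to rotation, for the first 160 units
only (the published detection limit). The two alleles superimpose; equal
sizes merge and heights (cosmetic, exponential decay) add.
Interpretation uses peak positions only: a maximal run of ≥10
consecutive unit-spaced peaks ⇒ motif present; runs of 1–9 ⇒
interruption; and a gap is flagged when ≥10 pentamer-equivalent unit
positions are uncovered by every assay in the panel with covered
positions on both sides. The standard panel assays AAAAG, AAAGG, AAGGG
and ACAGG; the extended panel adds AAGAC and AAAGGG.

**Short-read screen.** Reads are placed on the locus reference
(flank + (AAAAG)₁₁ + flank) by a unique 20-mer seed (ambiguous,
repeat-internal seeds do not place, like MAPQ-0 alignments), extended
outward, and clipped where >2 mismatches accumulate in a 15-base window —
chosen so an AAAGG allele (3 mismatches per 15 bp against the AAAAG
reference) clips while rare sequencing errors do not. The call logic uses
three signals, all surfaced in the result metadata because the published
criterion is visual inspection: (1) *reference-range spanning reads* —
left and right junction anchors in one read with an implied tract of
40–70 bp; ≥3 such reads ⇒ reference present; (2) the flank/repeat
*depth-drop ratio* (threshold 2×, flank windows 200 bp); (3) *junction
soft-clips* — reads mismatch-clipped within 5 bp of a flank/repeat
junction, the pileup an aligner shows at an expansion boundary. A sample
with zero spanning reads and either a depth drop or ≥3 junction clips is
*suspected biallelic*; anything else is *indeterminate* and routes to
follow-up testing. The junction-clip signal is essential for expansions
whose 5′ sequence matches the reference motif (e.g. pure AAAAG
expansions), which never produce an interior depth drop.

**Locus motif inventory.** Reads anchored at a flank junction and
extending ≥25 bp into the tract are decomposed into period-5/6 tandem
runs (autocorrelation); each motif with a run ≥25 bp is credited once per
read when the runs explain ≥80% of the repeat-adjacent segment. This
reproduces the known flank-proximity bias: a motif deeper than a read
length into the tract is never observed.

## Long-read decomposition

**Tract extraction** locates 30-bp flank anchors exactly, then
approximately (edlib, ≤6 edits — at the default error rates a 30-bp
anchor carries ~2.7 expected errors); unanchored reads are dropped and
counted.

**Segmentation** is a dynamic program over tract positions with one state
per candidate motif plus "unexplained". A motif state consumes p−2…p+2
bases per unit, scored per base consumed: 1.0 for an exact rotation
match, 0.5 within one edit, 0.25 within two (precomputed edit
neighbourhoods, so a unit hit by one or two errors still counts and the
register re-synchronises after indels). Scoring per base — not per unit —
is what lets pentamer and hexamer explanations of the same region compete
fairly. Two refinements deal with a genuine ambiguity of this motif
family: every 5-window of a period-6 tract is an exact rotation of some
pentamer (and vice versa), so (a) an exact unit followed by an identical
unit earns a small phase-consistency bonus (0.08/bp), which breaks
boundary ties in favour of the parse whose rotation phase is constant
within each block, and (b) each labelled run is checked by
autocorrelation and relabelled to the other period when that period
explains its sequence better by a margin of 0.1. Switching states costs
1.5 (bp scale), raised to 3.0 between motifs within one edit of each
other — a one-unit excursion to such a motif is sequence-identical to a
single substitution error, so those switches demand stronger evidence.
The penalties keep a single-unit interruption of a distant motif (e.g.
AAAAG inside AAGGG) recoverable: it gains 5.0 and pays 3.0. Runs whose
mean score per base falls below 0.65 (a wrong motif absorbing a region at
partial credit scores ≈0.5) are demoted to unexplained; unexplained
bursts ≤15 bp between same-motif runs are absorbed as error clusters.
Finally, runs of ≥10 units become segments (unit count = run bp /
period), runs of 1–9 units become interruption records, and adjacent
same-motif segments merge.

One identifiability limit is accepted rather than papered over: an
interruption whose motif is within one edit of its host block (e.g.
AGAGG inside AAAGG) is indistinguishable from a substitution error in a
single read, and blocks of exactly the 10-unit threshold can be demoted
by a single corrupted unit. Consensus across reads mitigates both; exact
per-read recovery is only guaranteed for error-free input.

**Novel-motif discovery** operates on regions where no known motif
reaches density 0.3. The density profile counts only phase-consistent
occurrences (an occurrence must repeat in register one period away),
again to defeat period aliasing. Candidate regions are scanned for
maximal tandem runs (s[j] = s[j+p]) at period 5, then 6 on bases not
already claimed by a pentamer; runs of ≥3 copies vote for their canonical
k-mer, and motifs explaining ≥10 units of candidate sequence are
returned, ranked by explained bases, never returning a known motif.

**Phasing** clusters tract lengths with deterministic two-means
initialised at the extremes; clusters merge when their means differ by
less than max(50 bp, 10% of the mean). When length clustering yields one
cluster but per-read segment orders split into two well-supported groups
(second group ≥ max(2, n/4) reads and the top group <80%), the sample
orchestrator re-splits by order: co-length heterozygotes are real at this
locus (a 625 bp AAAAG allele vs a 650 bp AAGGG+AGGGG allele) and
invisible to length alone.

**Consensus** takes the modal segment order across reads, per-segment
median copy counts over the modal reads, and interruptions present in a
majority of them (grouped by motif and index ±3). The total copy-count
estimate is the median of per-read unit estimates (labelled units plus
internal unexplained bp divided by the neighbouring period) with a
median-absolute-deviation spread; a single-read cluster reports an
undefined spread, and a tie in segment order falls back to the
longest read with a low-confidence flag. Segments within one edit of a
G-rich alternative (AAGGG/AGGGG) carry an ambiguity note.

## Diagnostic workflow and classification

The staged decision tree prefers the NGS screen when short reads are
available, else flanking PCR; contradictory screens yield an
indeterminate report. A reference-range allele ends testing (negative
report, with a recommendation to test other repeat-expansion disorders).
RP-PCR presence of only pathogenic motifs with no gaps supports a
positive report without sequencing; presence of only reference/benign
motifs with no gaps is a negative-with-caveat; anything gapped, empty or
mixed routes to long-read decomposition and structural classification.

An allele is pathogenic when it is a pure AAGGG or ACAGG expansion of
≥50 units (interruptions totalling ≤9 units tolerated) or matches the
Māori pattern (5′ AAAGG 15–25 copies, AAGGG ≥50, 3′ AAAGG 10 ± 2). The
50-unit floor is an operational default surfaced on every report — no
disease-causing size threshold is established for this locus, and the
cohort simulation keeps benign alleles above the floor so the floor
never decides a class. Genotype classes, in precedence order: biallelic
pathogenic; any allele below the floor ⇒ reference-present negative; one
pathogenic + one non-pathogenic expansion ⇒ carrier; any undetermined or
unregistered segment motif ⇒ novel/undetermined; else biallelic benign.
Loss-of-function variants in *RFC1* and testing for other
repeat-expansion disorders appear as report caveats, not calls.

## Cohort statistics

Percentages are 100·count/denominator rounded half-up to one decimal —
the convention that reproduces every published figure checked (15.3,
35.7, 31.1, 8.0, 53.7, 58.5, 52.4, 22.0, 6.1, 4.9). Denominators: the
full cohort for prevalence, subgroup size per subgroup, and
biallelic-expansion samples (n = 82 under defaults, including the
pathogenic ones) for motif prevalence and the complex fraction; motif
prevalence counts each sample once per motif because RP-PCR cannot phase
alleles. The published ataxia-subgroup figure is internally inconsistent
in its source (4.7% with n = 5 of 105 in one place, 3.8% in another;
neither equals 5/105 rounded); the module computes from supplied counts
and does not adjudicate.

## Problem sizes and verification

The test suite verifies: exact structure→sequence→structure round-trips
on a 55-structure corpus including the three consensus genotypes; copy-
count recovery within 5% median error at default noise for pure alleles
of 60, 125, 400 and 1000 units over 20 seeded replicates (8 reads each);
segment-order recovery of the consensus shapes in ≥95% of 60 noisy
replicates at 6× per haplotype; zero phasing misassignment for
well-separated alleles; screen concordance between the NGS and
flanking-PCR screens on a 42-sample subset spanning the published
genotype classes; and exact truth agreement of the full workflow on the
default 242-sample cohort at zero assay noise. Coverages of 4–8 reads
per haplotype were chosen as the point where consensus statistics
stabilise in these experiments; real targeted runs yield more.

## Known limitations

* Motif identity is rotation-only and plus-strand; no reverse-complement
  classes, by design.
* Per-read segmentation is not guaranteed exact under noise near block
  boundaries of aliasing motif pairs (AAGGG/AAAGGG, AAGGG/AGGGG);
  consensus copy counts for small blocks adjacent to such boundaries can
  be biased by a few units.
* The short-read screen is a quantitative surrogate for visual BAM
  inspection; biallelic expansions shorter than ~2 read lengths with
  reference-like 5′ sequence may still return indeterminate (which
  triggers follow-up testing, the safe direction).
* The RP-PCR model has no stutter, dye pull-up or ladder calibration;
  interpretation is position-only, as heights carry no information here.
* The consensus procedure is this package's own modal-order/median
  scheme, validated by round-trip and recovery properties rather than by
  concordance with any external caller.
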