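# Methods

This note documents the models behind each module, the defaults and why,
what the synthetic data do and do not emulate, and the numerical choices a
maintainer would want to know. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data (`lethalscan.synthetic_data`)

The generator defines the study conditions; downstream modules never see
real data.

**Genotypes.** A marker map of 5 chromosomes × 300 SNPs (~60 Mb each,
~200 kb spacing — a 50K-array-like density genome scaled down for runtime)
with per-marker allele frequencies drawn Uniform(0.1, 0.9). One carrier
haplotype is drawn once from the seed over the planted interval (default
2.46 Mb, ≥ 10 covering markers enforced). All cases carry it homozygous
across the interval and are random elsewhere; each control haplotype is the
carrier haplotype with probability *q* solving *2q(1−q) = c* and random
otherwise. The config's `carrier_freq` is the *diploid* carrier frequency
(the quantity a population screen reports, 7.4% by default); using it
directly as a haplotype frequency would double the fraction of carrier
animals. Controls homozygous for the planted haplotype are allowed to arise
naturally — the homozygote-deficit statistics need the unconstrained model.
Phase is retained for controls only; cases are unphased, as a diagnostic
lab would see them.

**Mate pairs.** Fragments (default insert Uniform(4,000, 4,500) bp,
matching the library's 4–4.5 kb fragment size; a normal option exists for
sensitivity analyses) are placed uniformly on the sample genome of the
chosen haplotype — the deleted haplotype is the reference with the deletion
excised — and 2×76 bp reads are mapped back to reference coordinates. Exactly
`round(coverage · L / (2 · read_length))` pairs are drawn. Three
consequences follow by construction rather than by modelling: no read of a
deleted haplotype overlaps the deleted reference interval; a
junction-spanning fragment maps insert + deletion-length apart; a read
crossing the junction carries the concatenated breakpoint sequence and is
emitted as a junction read instead of a mapped pair. The default window is
60 kb with a 3,329 bp deletion at 30,000 and 30× coverage (deep enough for
a base-exact dropout; the study's genome-wide 1.7× regime is exercised in
tests through the sparse-coverage dropout mode). No base-calling errors,
quality values, chimeras or repeats are simulated — the SV caller therefore
sees an idealised library, and passing tests say nothing about repeat-rich
or error-prone real data.

**Matings.** Four classes (dam's-sire × sire: NC×NC, C×NC, NC×C, C×C); the
sire's genotype is certain, the dam is known only through her sire: carrier
probability 0.5 + c/2 if carrier-sired, c/2 otherwise. The conceptus is D/D
when both parents are carriers and both transmit. Failure by day *t* uses a
single uniform *u* per mating: failure(t) = *u* < baseline(t) + 1{D/D}·m(t),
capped at 1. This coupling makes a dead conceptus always trigger a return
to oestrus and makes the expected class contrast equal P_hom·m(t)
*exactly*, which is the additive arithmetic the mortality estimator
inverts; an independent-OR coupling would attenuate the contrast by
(1 − baseline) and contradict the published additive accounting. The
closed form holds in the unsaturated regime baseline(t) + m(t) ≤ 1 (true
for the defaults); beyond it the cap binds and the realised contrast
shrinks, as it must when failure probabilities approach 1. Baseline
defaults are 0.35/0.40/0.45 at 56/90/270 d — the per-class published
tables are supplementary-only, so these are configurable stand-ins; they
cancel in contrasts, which the tests verify. Mortality defaults are
0.30/0.40/0.52: 52% cumulative by day 270 with more than half of the loss
before day 56. Culling without reported calving ("removers") is not
modelled; it is a known unquantified bias of the real non-return data, not
corrected here.

**FANCI-like gene case.** The real bovine FANCI exon coordinates and primer
sequences are not published in the study text, so `fanci_like_case()`
builds a synthetic 37-exon gene satisfying the published identities: coding
length 3,987 nt (1,328 residues + stop); exons 1–24 sum to 2,631 nt (877
codons, so the junction falls on a codon boundary); exons 25–27 sum to
361 nt (≢ 0 mod 3 → frameshift); a 3,329 bp genomic deletion removes
exactly exons 25–27; cDNA primers in exons 24/28 give 457/96 bp products
and a junction-spanning genomic pair gives a 409 bp deletion-specific
product. The post-junction coding sequence is redrawn (seeded rejection
search over non-stop codons) until the shifted frame yields exactly 26
novel residues before its stop, leaving the PTC in exon 28. Everything else
about the gene (intron sizes of 1 kb, flanks, base composition) is
arbitrary and random.

## Autozygosity mapping (`lethalscan.autozygosity`)

The point statistic for a segment shared homozygous-identical by *n* cases
is *p(s) = f^2n*, with *f = (matches + 1)/(2N + 2)* the add-one-smoothed
frequency of the case haplotype among the 2N phased control chromosomes
(pseudocount configurable; add-one keeps *p* strictly positive when the
haplotype is absent from the pool). The genome-wide null redraws 2n
chromosomes with replacement from the control pool per replicate, reruns
the identical scan, and records the genome-wide minimum *p*; the reported
probability is the add-one Monte-Carlo estimator
(1 + #{null minima ≤ observed})/(n_reps + 1), floored at 1/(n_reps + 1).
Defaults: `min_markers=20`, `max_het=0`, `pseudocount=1`, `n_reps=1000`.

Numerical choices: missing genotypes always break runs (a gap is never
assumed homozygous); the control pool is sorted lexicographically before
resampling, which makes the null draws — and hence the reported
probability — exactly invariant to the order in which control individuals
are supplied; ROH maximality with a heterozygote budget is computed from
the het-position bounds (each maximal window contains exactly `max_het`
heterozygous calls when more are available).

Known limitation: cases from a live pedigree are related beyond the causal
locus, which the resampled-chromosome null ignores; the statistic is
therefore anti-conservative genome-wide. This mirrors the design being
emulated and is documented rather than corrected. Controls must be supplied
phased (the generator emits truth phase); no phasing or imputation is
attempted.

## Deletion calling (`lethalscan.sv_calling`)

The insert model takes the mean/sd of the central quantiles
(`trim_quantile=0.05` per side) of mapped distances and sets the
discordance threshold at mean + 4·sd (the study judged discordance
visually; k = 4 separates a 4,000–4,500 bp library from pairs inflated by
any multi-kb deletion), floored 1 bp above the mean so degenerate
zero-variance libraries still satisfy threshold > mean. In the pipeline
the model is fitted on the wild-type control library and applied to the
case — as in a case/control sequencing design — which also keeps the
trimmed mean clean of deletion-spanning pairs when those exceed the trim
fraction. Only FR-orientation pairs enter clustering (inversions are out of
scope). A pair's breakpoint-compatible interval is (end of read 1, start of
read 2); chains overlapping within `max_gap=1000` form a cluster whose
interval is the intersection of member intervals (it contains the deletion
and tightens with support) and whose size estimate is mean distance −
insert mean.

Dropout detection: homozygous mode finds maximal zero-depth runs ≥
`window` (500 bp default) whose flanking windows average ≥
`min_flank_depth` (0.5×, low enough to accept 1.7×-coverage flanks);
heterozygous mode bins the track and takes runs of bins within 0.3–0.7× of
the track median — deliberately simple, the study only used homozygotes.
Cluster and dropout merge at reciprocal overlap ≥ 0.5; merged calls take
the dropout's base-resolution coordinates.

Breakpoint refinement is exact-match seed-and-extend (20-mer anchors,
±2 kb search windows): junction reads are simulator-clean, so no gapped
aligner is needed; a read that fully matches the reference, anchors
ambiguously, or fails to anchor on both sides simply does not vote, and a
call with no voting read is returned unrefined. The greedy prefix extension
right-aligns the junction through any microhomology; calls are then
left-aligned, and the reported microhomology is the total junctional
ambiguity (identical run lengths immediately left plus immediately right of
both breakpoints; 0 is an expected value for random breakpoints).
Coordinates are 0-based half-open internally, 1-based symbolic `<DEL>` on
VCF output.

## Consequence prediction (`lethalscan.consequence`)

Only deletions removing whole exons are supported; a deletion splitting an
exon raises rather than guesses (the modelled case deletes whole exons).
Strand is handled by projecting into transcript coordinates. The mutant
CDS keeps the wild-type ATG and is translated to its first stop; a
frameshift is flagged iff the summed deleted coding length ≢ 0 mod 3
(verified in tests against direct translation of both sequences). The
divergence position is the first residue where the two proteins differ;
truncated residues = wild-type length − (divergence − 1); the novel
peptide runs from the divergence to the mutant stop. The NMD rule is the
50-nt rule, *inclusive* at the boundary (a PTC exactly 50 nt upstream of
the last junction is flagged; a 55-nt variant is configurable); single-exon
transcripts are never substrates. PCR product size is the distance between
primer 5′ ends inclusive; a primer matching a template more than once is an
error rather than a guess, and products above `max_amplicon` (5 kb default
on genomic DNA) are reported as no-product.

## Population genetics (`lethalscan.popgen`)

Carrier frequency uses the Wilson score interval (accurate for small
proportions where Wald degenerates). Expected incidence defaults to the
carrier-pairing approximation c²/4 — the form behind the published
"1 in 730" — with the exact HWE q² available via a flag; the two differ by
(1−q)⁻² ≈ 8% at c = 0.074. The homozygote-deficit probability is the exact
binomial zero-class (1−q²)^N. The survival-adjusted reciprocal incidence
is rounded to the nearest 100 above 1,000 (nearest 10 below); the raw
reciprocal is returned alongside.

## Fertility contrasts (`lethalscan.fertility`)

Contrasts are additive risk differences, not odds ratios, because the
quantity being inverted is an absolute excess over the NC×NC reference.
Per class and stage, a 2×2 chi-square without continuity correction is
used, switching to Fisher's exact test when any cell is below 5; raw
p-values are reported with no multiplicity correction (three stages ×
three classes is the entire family and the consumer sees all of them).
m̂(t) = excess(t)/P_hom is clipped to [0, 1]; confidence intervals come
both from the delta method on the rate difference (binomial variances of
the two class rates) and from a parametric bootstrap redrawing class
failure counts (200 draws by default); P_hom is treated as known, since it
derives from the genotyped sire and the population carrier frequency.
Cumulative-mortality monotonicity over stages can be enforced on the point
estimates with an isotonic flag (off by default; the raw estimates are the
honest moments). The excess observed in the real data for carrier-dam ×
non-carrier-sire matings cannot be produced by the recessive-lethal model;
the package surfaces that class's excess as a model-misfit diagnostic and
deliberately fits nothing to it.

`recover_parameters` runs the simulate → contrast → estimate loop and
reports bias, RMSE and delta-CI coverage; the acceptance suite runs it at
10⁵ matings per class × 200 replicates.

## Pipeline (`lethalscan.pipeline`, `lethalscan` CLI)

One root seed; each stage's seed is SHA-256-derived from (root, stage
name), so stages are independently rerunnable and a rerun is bit-identical.
The manifest stores stage seeds and SHA-256 digests of every output and
contains no wall-clock information, so identical runs produce identical
manifests. A stage failure aborts the run with the stage named and leaves a
`.partial` marker. Default problem sizes (1,500 markers, 100 controls,
1,000 scan replicates, 60 kb read window at 30×, 10⁵ matings per class,
3,038-animal popgen sample) complete in a few seconds on one CPU; the
analysis scripts and acceptance targets use 10⁶ matings per class where the
contrast precision matters. In the report, the genomic junction-spanning
amplicon is evaluated with `max_amplicon=2000` so that the wild-type span
(deletion + 409 bp) correctly yields no product, emulating a short-cycle
assay.

## Known limitations

* The Monte-Carlo mapping null ignores case relatedness (anti-conservative).
* The read simulator has no errors, repeats, or chimeric artefacts; SV
  results validate algorithmic structure, not robustness to real libraries.
* Mating outcomes are exchangeable Bernoulli records: no herd, season,
  parity or sire effects, no "removers", no days-open survival modelling.
* Partial-exon deletions, splice-site scoring and protein-domain mapping
  are out of scope for consequence prediction.
* The expected number of discordant pairs at 1.7× physical coverage is
  dataset-dependent; only its order of magnitude is meaningful here.
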