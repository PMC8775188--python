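# Methods

## The assay being modelled

A massively parallel splicing-reporter (minigene) screen measures, for
each de novo coding SNV, whether the mutant allele splices its host exon
differently from the wild-type allele. Wild-type/mutant pairs of 230-mer
oligos (a 180-nt genomic insert — upstream intron, test exon of at most
115 nt, 15-nt downstream flank — between 25-nt primer arms) are cloned
into three-exon reporters, transfected, and both the input plasmid pool
and the spliced output are deep-sequenced. The three reporter backbones
differ in the 5' splice-site strength of the first exon (MaxEntScan
10.15, 8.35 and 6.66 for the strong, intermediate and weak versions) and
share one terminal exon; a stronger upstream donor amplifies skipping of
the downstream test exon.

Per variant and construct the statistic is the allelic imbalance

    ratio = log2( (m_o / m_i) / (w_o / w_i) )

with `m_o`, `w_o` the mutant/wild-type spliced-output counts and `m_i`,
`w_i` the input counts. Dividing by input abundance cancels synthesis
bias between alleles. Significance per construct is a two-sided Fisher
exact test on the 2x2 table (allele x output/input), adjusted by
Benjamini–Hochberg within the construct; a hit needs q < 0.05 and at
least a 1.5-fold allelic ratio in either direction, and a screen-level
hit is significance in at least one construct.

## Species model and counting

The species universe per variant, allele and construct is fixed to three
transcripts: the unspliced pre-mRNA (input), the three-exon inclusion
product, and the two-exon skipping product. Cryptic splice sites and
partial intron retention are out of scope — minigene readouts are
dominated by the inclusion/skipping dichotomy, and complex endogenous
events are explicitly beyond what this reporter architecture can
resolve.

Classification of reads is exact-window scanning with mismatch counting
(default tolerance 3 mismatches, mirroring common amplicon-alignment
settings) against the enumerated species, seeded by tiling 25-mers. No
heuristic aligner is used: the species are short, fully enumerated, and
a read is assigned only when its best window beats every alternative
window by at least one mismatch (the analogue of a unique-mapping
filter). Input-library reads may only be assigned to the pre-mRNA
species; junction-containing reads in the input are discarded with
reason `split_in_input`. Output reads may only be assigned to spliced
species; reads matching only the pre-mRNA are discarded with
`no_junction_support`. Paired mates must agree or the fragment is
ambiguous.

Two consequences of the construct architecture are handled explicitly:

* Because the three backbones share the library insert verbatim, a read
  lying inside the insert cannot identify the backbone. Each construct
  is therefore treated as its own sequencing library (as the separate
  transfections imply) and classified against that construct's records
  only.
* The skipping product (first exon joined to terminal exon) contains no
  insert-derived sequence, so skip reads identify neither the allele nor
  the variant. They are tallied per construct as diagnostics and never
  enter the four counts; `m_o`/`w_o` count inclusion-product reads,
  which are allele-resolved. The imbalance therefore measures change in
  inclusion, with negative values indicating more skipping of the
  mutant allele.

## Synthetic-data generator

Ground truth per (variant, construct) is: the wild-type inclusion
fraction `psi_wt` (uniform on [0.5, 0.9] by default), the mutant
fraction `psi_mut`, a mutant:wildtype synthesis bias `b` (log-normal,
sigma 0.25, or fixed), and the construct's skipping-odds boost. A
configurable fraction of variants (default 10%) is splice-disrupting:
their mutant inclusion is lowered by a configurable log2 shift (default
one unit); shifts can also be supplied per variant, e.g. proportional to
an enhancer-score change. The boost enters as
`psi' = psi / (psi + (1 - psi) * k)`, i.e. a multiplier `k` on the odds
of skipping; the shipped defaults are k = 2.5, 1.6 and 1.0 for the
strong, intermediate and weak backbones, chosen to produce a clear,
strictly ordered amplification of |imbalance| while leaving the weak
backbone at the unboosted baseline. The closed-form expected imbalance
is `log2(psi'_mut / psi'_wt)`; the bias `b` cancels.

Counts are multinomial at fixed library size (default 4,000 reads per
variant, construct and library — 2,000 per allele at unit bias), so read
totals are conserved exactly per simulation; a Poisson model was
rejected to keep that conservation exact. Reads are drawn from the
species sequences with uniform substitution-only error (default 0.001
per base; indels are out of scope for mismatch-based classification).
For allele-bearing species the fragment is drawn to cover the variant
position, emulating amplicon-style coverage of the informative site;
skip-product fragments start uniformly. One explicitly seeded RNG stream
drives each simulation object; a fixed seed yields byte-identical FASTQ.

What the generator does **not** emulate: PCR duplicates, quality-score
structure, indel or context-dependent errors, cryptic splice products,
partial splicing intermediates, and construct-specific transfection
efficiencies. Passing tests therefore demonstrate the correctness and
operating characteristics of the counting and statistics under the
stated model, not performance on real sequencing artefacts.

The synthetic cohort generator mirrors the screened cohort's shape:
447/725 of variants from probands, consequence classes ~30% synonymous,
62% missense, 8% nonsense, exon lengths uniform over the eligible range,
uniform random sequence. Primer arms, backbone sequences and the
demonstration enhancer-index table are synthetic, fixed-seed stand-ins
(the real plasmid sequences and the empirical hexamer table are not
redistributed); all coordinates derive from the recorded part maps.

## Enhancer-index scoring

An exon's enhancer index is the mean of its L−5 overlapping hexamer
scores, looked up in a user-supplied table; the per-variant change is
the wild-type mean minus the mutant mean (positive = enhancer loss).
Only exon-interior windows are scored — windows straddling the
exon/flank boundary are excluded, since the table quantifies exonic
enhancer activity. Because alleles differ at one base, at most six
windows contribute to the difference; the implementation recomputes both
means in full and a test checks the window-local shortcut agrees.

## Numerical choices and edge cases

* Zero counts: a Haldane–Anscombe pseudocount of 0.5 is added to all
  four counts only when at least one is zero; nonzero tables are never
  perturbed. Fisher runs on raw counts. An all-zero row yields a NaN
  ratio and is never significant.
* FDR family: all variants within one construct, since per-construct
  hit sets are reported; this is an interpretive choice.
* "1.5-fold" is applied two-sided (|log2 ratio| >= log2 1.5), so
  gain-of-inclusion variants can be hits.
* Mann–Whitney uses the normal approximation with continuity and tie
  correction; Kruskal–Wallis the chi-square approximation. Fully
  degenerate inputs (all values identical) return p = 1 rather than
  raising.
* Eligibility is exon <= 115 nt and >= 50 nt of retained upstream
  intron; the intron is trimmed from its distal end to make the insert
  exactly 180 nt. Only SNVs inside the exon are accepted; multi-
  nucleotide variants and flank-positioned variants are rejected loudly.
* Minus-strand genes: contexts are stored reverse-complemented into
  transcript orientation and the reader verifies the strand-adjusted
  reference allele, so every downstream stage works in one orientation.

## Problem sizes used in tests

The test suite and the acceptance script run the read-level round trip
at 200 variants x 3 constructs x 4,000-read libraries (about 4.8 million
reads), counts-level null and ordering checks at 200–400 variants, and a
full-cohort-size (725-variant) synthetic screen for the proportion
summaries. These sizes give Monte-Carlo error well inside the asserted
tolerances while keeping a complete run to a few minutes on one core.

## Known limitations

* The classifier assumes enumerable species; it is not a general spliced
  aligner and will not discover unexpected junctions.
* Skip products are unattributable to variants by construction, so
  per-variant skipping rates are not estimable from this design; only
  inclusion-based imbalance is.
* The screen has no replicate structure, so no dispersion model is
  fitted; Fisher's test treats counts as the only noise source.
* External splicing-model scores and paralog annotations are consumed as
  given; the package neither computes splice-site strengths nor predicts
  scores.
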