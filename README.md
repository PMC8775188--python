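# mapsy

Analysis toolkit for massively parallel splicing-reporter (minigene)
screens of de novo coding variants, built for studies asking whether
seemingly benign exonic SNVs — especially synonymous ones seen in
affected children but not their parents — disrupt splicing of their host
exon.

The screen compares each mutant allele against its wild-type counterpart
inside three-exon reporter constructs. Wild-type/mutant 230-mer oligo
pairs (a 180-nt genomic insert between 25-nt primer arms) are cloned
downstream of a first exon whose 5' splice-site strength varies between
backbones (strong / intermediate / weak donors), the input pool and the
spliced output are sequenced, and the per-variant statistic is the
**allelic imbalance**

```
ratio = log2( (m_o / m_i) / (w_o / w_i) )
```

where *m*/*w* index the mutant and wild-type allele and *o*/*i* the
spliced-output and input counts. Input normalisation cancels synthesis
bias between alleles. Per construct, a two-sided Fisher exact test with
Benjamini–Hochberg adjustment and a 1.5-fold threshold calls
splice-disruptive variants; a screen-level hit is significance in at
least one construct. Downstream modules score exonic-splicing-enhancer
(hexamer EI) changes, and compare probands against unaffected siblings
(hit proportions by consequence class, rank tests, gene-set burden,
primary-set/paralog gene summaries).

The package covers the full loop: library design, a ground-truthed
sequencing simulator, junction-aware read classification against the
enumerated species catalog (unspliced input, exon inclusion, exon
skipping), the imbalance statistics, and the cohort comparisons. See
`docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Run the seeded end-to-end demo (design -> simulate -> quantify -> stats
-> cohort on 24 synthetic variants):

```
$ mapsy demo --out-dir demo_out --seed 7
demo complete: 24 variants, 8 screen-level hits; outputs in demo_out
```

`demo_out/results.tsv` holds one row per variant and construct. The top
calls look like:

```
       variant    construct  mo  mi  wo  wi     ratio            p            q  n_constructs_significant
20:1008469:G:T       strong  39 336 195 264 -2.669851 2.533645e-26 6.080749e-25                         3
 2:1022604:T:G       strong  28 283 189 317 -2.591207 9.233755e-21 1.108051e-19                         3
 5:1011464:T:C intermediate  37 363 131 236 -2.445152 3.055437e-19 5.906351e-18                         3
```

Reading the first row: of the mutant allele's reads in the strong-donor
construct, 39 spliced-output (exon-inclusion) reads against 336 input
reads, versus 195/264 for the wild type — the mutant allele includes the
exon about 2^2.67 ≈ 6-fold less than wild type (`ratio` −2.67), Fisher
p = 2.5e-26, BH q well under 0.05, and the variant is significant in all
three constructs (`n_constructs_significant` = 3): a clear
splice-disrupting hit. Null variants sit near ratio 0 with q ≈ 1.

The same stages are available as separate subcommands (`mapsy design`,
`simulate`, `quantify`, `stats`, `cohort`) and as library functions
(`mapsy.pipeline`, `mapsy.simulate`, `mapsy.quantify`, `mapsy.stats`,
`mapsy.ese`, `mapsy.cohort`).

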