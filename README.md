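# acetylstoich

Site-level **lysine acetylation stoichiometry** from heavy/light
chemical-labeling DIA proteomics, with the statistics needed to compare
acetylomes across experimental groups.

## The problem and who this is for

In a stoichiometry experiment, every lysine that is *not* endogenously
acetylated is chemically acetylated with D6-acetic anhydride before
digestion. Each lysine then carries either an endogenous **light** acetyl
(CH3-CO, +42.0106 Da) or a chemical **heavy** acetyl (CD3-CO, +45.0294 Da),
and the occupancy of a site is directly readable from paired fragment-ion
peak areas:

```
s = L / (L + H_corr),   H_corr = max(0, H_obs - L * r),   r = a_3k / a_0
```

where `L` and `H_obs` are the light and heavy fragment peak areas and `r`
is the natural-isotope leakage of the light fragment into the heavy channel:
at DIA resolution the +3k isotopologue of the light species (three ¹³C for
each of the k labels covered) is not resolved from the heavy monoisotopic
peak, so `L·r` must be subtracted. This package is for proteomics analysts
who have fragment-level light/heavy quantification (e.g. from a DIA tool fed
with an in-silico heavy/light spectral library) and need the downstream
analysis: pair generation, envelope correction, site aggregation, group
statistics, and pathway over-representation.

What it provides:

- **`chem` / `peptides`** — elemental compositions with a shipped isotope
  table (including pure-²H label positions), monoisotopic masses, isotope
  envelopes by nominal-offset convolution, trypsin+GluC digestion with
  acetyl-blocked lysines, b/y fragment m/z, and in-silico heavy/light
  fragment-pair tables with correction ratios.
- **`quantify`** — envelope correction, per-fragment stoichiometry, and
  median aggregation to site × replicate values using only site-informative
  fragments (those covering exactly one lysine).
- **`stats`** — per-peptidoform one-way ANOVA across groups combined per
  site with Fisher's method (`-2 Σ ln p ~ χ²(2k)`), BH FDR, two-sample KS,
  volcano tables and Venn-style model-overlap summaries.
- **`enrichment`** — fold enrichment `(k/n)/(m/N)` with upper-tail
  hypergeometric p-values and BH FDR over a detectability-conditioned
  background.
- **`simulate`** — a ground-truthed synthetic study generator (three groups
  × five replicates, >99% labeling, log-normal noise, missingness, planted
  effects with a configurable shared fraction) used throughout the tests.

## Worked example

`examples/02_stoichiometry_pipeline.py` simulates an 80-site study and runs
the full analysis:

```
quantified 80 sites (1187 site x replicate rows, clamp rate 0.0031)
sTgA vs WT: 79 sites tested, 22 significant at p < 0.05
sTgB vs WT: 79 sites tested, 23 significant at p < 0.05
significant-site overlap: 9 shared, 13 unique to sTgA, 14 unique to sTgB
power on planted sTgA effects: 1.00; false-positive rate on null sites: 0.050
```

The clamp rate is the fraction of fragments whose heavy area fell below the
correction term (floored at zero); the overlap line is the input to a Venn
diagram of the two models; power/FPR compare the significant calls against
the generator's planted truth. `examples/01_fragment_pairs.py` prints the
in-silico pair table for one protein and `examples/03_enrichment.py` shows a
planted 5-fold-enriched category recovered by ORA
(`fold_enrichment 5.33, q_bh 6.4e-20`).

The same pipeline is scriptable from the shell:

```
acetylstoich simulate --out sim --n-sites 200 --seed 1
acetylstoich quantify --fasta sim/proteins.fasta --quant sim/quant.tsv --out run
acetylstoich test --sites run/site_stoichiometry.tsv \
    --peptidoforms run/peptidoform_stoichiometry.tsv \
    --model sTgA --model sTgB --out run
acetylstoich enrich --comparison run/comparison_sTgA_vs_WT.tsv \
    --annotations sim/annotations.tsv --out run/enrichment.tsv
acetylstoich report --dir run --out report.txt
```

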