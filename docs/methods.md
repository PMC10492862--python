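# Methods

## Measurement model

A stoichiometry experiment chemically acetylates every unmodified lysine
with D6-acetic anhydride, so after labeling each lysine carries exactly one
acetyl group: endogenous light (CH3-CO, +42.010565 Da) or chemical heavy
(CD3-CO, +45.029395 Da). For a fragment ion covering k acetyl-lysines the
heavy form sits 3k × 1.0062767 Da above the light form (per charge), and the
endogenous occupancy of the site is

    s = L / (L + H_corr),  H_corr = max(0, H_obs − L·r),  r = a_3k / a_0,

with L and H_obs the light and heavy peak areas and r the natural-isotope
leakage ratio of the light fragment: at the resolution of DIA fragment
quantification the +3k isotopologue of the light species (dominated by ¹³C
substitutions) coincides with the heavy monoisotopic peak. The assumptions
are (i) light and heavy species co-elute and ionize identically (the label
adds only neutrons), (ii) peak areas are proportional to the underlying
species amounts, and (iii) labeling is essentially complete, so no third,
unmodified lysine population contributes signal.

## Chemistry layer

Compositions, masses and envelopes use a fixed isotope table
(IUPAC-2013-style masses and abundances for C, H, N, O, S, plus a pure-²H
pseudo-element `D` for label positions) shipped with the package so results
never depend on the runtime environment. Envelopes are indexed by *nominal*
mass offset (integer Da) and computed by convolving per-element isotopologue
distributions, each raised to its atom count by exponentiation-by-squaring;
this is exact for the retained offsets because offsets only add. Envelopes
are truncated at `max_iso = max(10, 3k+2)` or at the first offset where the
cumulative abundance reaches 1 − 1e-9, whichever comes first, and reported
values are fractions of the untruncated total (never renormalized after
truncation). Nominal-offset indexing is the right granularity here because
the correction targets exactly the +3k nominal coincidence; fine isotopic
structure is far below DIA resolution.

Digestion models trypsin + GluC with acetyl-blocked lysines: cleavage
C-terminal to R and E, never after K, suppressed before proline (standard
convention; configurable). GluC specificity defaults to E-only with an E+D
switch, since the buffer-dependent behavior is rarely known. Peptide length
bounds default to 6–30 residues and fragment charges to {1, 2} — typical
search-engine settings. Coordinates are 1-based inclusive everywhere; a site
is identified by (protein accession, lysine position in the protein).

## Quantification rules

- Only *site-informative* fragments — those covering exactly one lysine —
  enter site-level values; fragments spanning ≥2 acetyl-lysines cannot
  localize the signal and are discarded.
- Site × replicate stoichiometry is the **median** across informative
  fragments, peptidoforms and charges (mean available via option); the
  median keeps a single interfered fragment from dominating.
- A site × replicate row requires ≥3 contributing fragments
  (`min_fragments`), so one noisy fragment cannot create a site.
- Over-corrected heavy areas (H_obs < L·r) are clamped at zero and flagged;
  the clamp rate is reported as QC. Negative areas are physically
  meaningless, and clamping introduces negligible bias at realistic r.
- Residual unlabeled lysine (chemistry failure) is indistinguishable from
  light signal, biasing s upward by at most 1 − η; the labeling QC
  (`qc_labeling`) warns when the observed labeled fraction drops below 0.99.

## Statistics

For each site, a one-way ANOVA (stoichiometry ~ group, no covariates) is
run per peptidoform across the compared groups, and the per-peptidoform
p-values are combined with Fisher's method (X = −2 Σ ln pᵢ ~ χ² with 2k df).
Fragments within one peptidoform share precursor and chromatography and are
strongly dependent, so they are first collapsed to one value per peptidoform
× replicate; distinct peptidoforms are treated as approximately independent
measurements of the site, which the type-I calibration test checks
empirically (global-null simulation, 1000 sites × 5 replicates: the
fraction of sites with combined p < 0.05 must fall in [0.03, 0.07]).

Sites must be quantified in ≥3 replicates of every compared group
(`min_replicates`) to be tested; sites detected in only some genotypes are
reported in a presence/absence table instead. Significance is flagged at
unadjusted p < 0.05 to match the usual volcano-plot convention, with BH
adjusted q-values always written alongside. Distribution shifts between two
sets of changes use the two-sample KS test (exact null for n ≤ 10 per
sample, asymptotic otherwise). Model-vs-model overlap reports shared/unique
significant sites and proteins; a direct model-vs-model comparison is the
same machinery with those two groups.

## Enrichment

Standard over-representation: hits k of a list of n significant proteins in
a category of m members within a universe of N, fold enrichment
(k/n)/(m/N), p = P(X ≥ k) hypergeometric, BH across all tested categories.
The universe is the set of proteins with ≥1 quantified site (conditioning on
detectability), categories with <2 members in the universe are dropped, and
display filters (q < 0.05, fold > 5, top 10 by fold, ties broken by
ascending q then category id) mirror the usual pathway-bar presentation.
Note that with a detectability-conditioned universe the attainable fold is
capped at N/n: when a third of the quantified proteins is significant, no
category can exceed fold ≈ 3. Published bar charts with fold > 5 typically
use a whole-genome background; both uses are supported by passing the
desired universe.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- Random protein sequences (default 60 proteins of 250–450 residues) with
  residue frequencies giving abundant single-lysine 6–30mers after
  digestion; max one missed cleavage for the quantified species (library
  searches tolerate more, but multiply missed-cleaved peptides are rarely
  the quantified evidence).
- Three groups — a reference (WT) and two overexpression models — with
  5 replicates each; 200 sites by default.
- Baseline stoichiometries ~ Uniform(0.05, 0.95). Per model,
  25% of sites receive a true shift |δ| ~ Uniform(0.05, 0.30) with random
  sign (clipped to [0.01, 0.99]); 30% of each model's affected sites are
  shared with the other model, echoing the partial-overlap design the
  statistics must resolve.
- Signal: per fragment × replicate a latent total T ~ log-normal
  (median 1e5, log-sd 0.5); light = T(sη + 1 − η) with labeling efficiency
  η = 0.995 (>99% labeling; failures booked as light — the conservative
  worst case), heavy = T(1 − s)η plus the envelope leakage L·r injected
  with the fragment's true ratio; independent mean-1 log-normal noise with
  CV = 0.10 on each channel; 5% of rows dropped completely at random.
- One-call bundles (`make_study`) add a labeling-QC table and a category
  annotation file with one planted category concentrated on affected
  proteins. For the fold-5 planted-category recovery check a dedicated
  generator (`simulate_enrichment_study`) builds an 800-protein universe
  with 120 significant proteins, where a genuine fold-5 category is
  arithmetically possible (see the cap above).

Everything is deterministic given the config seed (one `numpy` Generator
stream). What the generator does **not** emulate: co-elution interference
between peptides, charge-state- or RT-dependent response, group-dependent
(informative) missingness by default, protein-abundance changes (stoichiometry
is self-normalizing by construction), or real pathway structure. Passing
tests therefore demonstrate correctness of the estimator and calibration of
the statistics under the stated error model, not robustness to every
pathology of real DIA data.

## Numerical choices and degenerate inputs

- Fisher combination floors p = 0 at the smallest positive double (logged).
- ANOVA on completely constant data returns F = 0, p = 1 rather than NaN.
- Fragments with zero total area are dropped (stoichiometry undefined).
- Full-length "b_n" masses are allowed for bookkeeping; pair generation
  only enumerates indices 1..n−1.
- Envelope ratios beyond the stored envelope length are 0 (no isotopologue
  at that offset).
- Study sizes in tests and in the acceptance script (200-site default
  study; 75 proteins / 1000 sites for the null calibration; 100 repetitions
  for detection rates) were chosen as the smallest sizes at which the
  binomial/Monte-Carlo error of the checked quantities is well inside the
  asserted bands.

## Known limitations

- Single-ratio correction: only the a_3k/a_0 leakage is subtracted;
  integrating several heavy isotopologues would slightly improve precision
  for large fragments.
- Labeling inefficiency is a small positive bias (≤ 1 − η) rather than a
  corrected term, matching the >99%-labeling QC framing.
- Peptidoform independence in Fisher's method is an approximation; shared
  interference across peptidoforms of one site would make the combined p
  anti-conservative.
- No mixed-effects or empirical-Bayes moderation; each site is tested
  marginally.
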