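# ednakit

Downstream analysis of marine vertebrate eDNA metabarcoding surveys: from
BLAST hit tables and PCR-replicate read counts to decontaminated community
matrices, habitat discrimination statistics, and species-accumulation
estimates of total diversity.

The package is aimed at molecular ecologists running seawater eDNA surveys
in which two mitochondrial 12S markers (a fish-targeted and a
vertebrate-targeted barcode) are amplified from replicated water samples
collected across habitat types, together with field, extraction and PCR
negative controls. Everything downstream of denoising is covered; read QC,
denoising and running BLAST itself are out of scope.

## What it computes

**Taxonomic assignment with data-driven thresholds.** Hits are screened at
≥90% query coverage and ≥80% identity, at most 40 per query. For each query
the mean percent identity of its hits at each relationship level relative
to the best-hit anchor (congeneric, confamilial, ordinal) is pooled across
queries, and the 95th percentile of each pooled distribution sets the
assignment thresholds: the identity of sequences from *different* species
in one genus bounds the species call (the species band itself is fixed at
99–100%), confamilial identities set the genus minimum, ordinal identities
the family minimum. Assignment proceeds by a tie-aware cascade
(species → genus → family), with ties among best hits broken in favour of a
unique regionally-present taxon on a checklist.

**Decontamination.** Three filters with a machine-readable audit ledger:
a blacklist of known contaminants (domestic animals, previous lab work),
matched through the taxonomy so ancestors remove descendants; removal of
any taxon whose maximum relative abundance in a negative control reaches
its maximum in any water sample; and a replicate-support filter discarding
taxa seen in a single PCR replicate (or, optionally, fewer than 3 of 4
replicates within each water sample).

**Community structure.** Replicates are rarefied without replacement to the
median per-PCR read depth and aggregated to water samples or sites. The
Raup–Crick dissimilarity between sites *j, k* with observed shared-species
count *s*<sub>obs</sub> is

&nbsp;&nbsp;RC(j,k) = 1 − [#(s<sub>null</sub> &lt; s<sub>obs</sub>) + ½·#(s<sub>null</sub> = s<sub>obs</sub>)] / n<sub>sim</sub>,

with null communities preserving each site's richness and drawing species
without replacement proportionally to their occurrence frequency (or
equiprobably, for which the null shared count is hypergeometric and the
index has a closed form). Bray–Curtis handles the abundance-based view;
UPGMA clustering, PERMANOVA (pseudo-F computed directly from squared
dissimilarities), a PCoA-based dispersion-homogeneity test with
inverse-normal transformation when violated, and CAP (LDA on leading PCoA
axes, scored by leave-one-out allocation success) quantify habitat
discrimination.

**Coverage of diversity.** Exact analytic species-accumulation curves,
E[S(n)] = Σ<sub>i</sub> [1 − C(N−f<sub>i</sub>, n)/C(N, n)], four
species–area models (Arrhenius, Gleason, Gitay, Lomolino) fitted by
multi-start least squares, AIC selection, and extrapolation of the winner
to 200 sites with the detected fraction of the fitted asymptote.

**Synthetic data.** `ednakit.synthetic_data` generates the whole input
bundle — taxonomy, BLAST-style hits whose identities decay with taxonomic
distance, lognormal-Poisson read counts with gamma-distributed replicate
depths, habitat-structured occupancy, and controls carrying known
contamination — with full ground truth, so every stage has a known-answer
test bed.

## Worked example

The numbered scripts under `analysis/` replay a complete two-season,
two-barcode survey over 24 sites in six habitat types (run them in order
from the repository root; outputs land under `results/`):

```text
$ python analysis/01_simulate.py
[2016] 150 pool species, 150 occupying >=1 of 24 sites; per-replicate depth
median 2250 (range 222-8029); 3 control contaminants, 3 domestic taxa injected

$ python analysis/02_assign.py
[2016/mifish] 1640 screened hits over 156 variants; 156 species-level calls;
thresholds mifish: genus >93.36%, family >89.38%, species [99,100]

$ python analysis/03_filter.py
[2016] 156 -> 150 taxa; removals by reason: blacklisted=3, control_frequency=3

$ python analysis/05_betadiv_multivar.py
[2016] dispersion p = 0.044 (transformed before PERMANOVA); habitat explains
100% of variation (PERMANOVA p = 0.001); CAP LOO success 100% at m = 3

$ python analysis/06_accumulation.py
[2016] observed 128 taxa over 20 surface sites; best model lomolino
(AIC 34.5); predicted 140 taxa at 200 sites; detected 91% of the estimated
total (140)
```

Reading the output: thresholds calibrated from the simulated hit tables
land just above the generating identity levels (genus >93%, family >89%);
the filters remove exactly the six injected contaminant taxa and nothing
else; habitat type explains essentially all Raup–Crick variation in this
strongly habitat-structured simulation (the real-data analogue is lower);
and the Lomolino model wins the AIC competition, putting the 20-site survey
at 91% of its estimated asymptotic richness.

A `ednakit` CLI exposes the same stages (`simulate`, `calibrate`, `assign`,
`filter`, `rarefy`, `dissim`, `permanova`, `accum`); see `ednakit --help`.

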