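# Methods

## The measurement problem

A single cytidine in a coding transcript is deaminated to uridine in a
fraction f of mRNA molecules; sequencers read the edited base as T.
The quantity of interest is f per sample, typically between 0.4% and
50%, which must be separated from per-base sequencing error (order
0.1%) and, for PCR-based assays, from imperfect allele discrimination.
The package implements four independent routes to f (RNA-seq pileup,
allele-specific qPCR, deep amplicon sequencing, semi-quantitative
RFLP), the coordinate arithmetic tying the site to genome, codon and
restriction map, and the nonparametric statistics used to compare f
across paired donor cultures.

## Gene model and coordinates

`GeneModel` stores exons and CDS intervals as 0-based half-open
genomic intervals plus the CDS in transcript orientation; c. numbering
starts at the first base of the start codon (HGVS convention; UTRs are
representable but un-numbered). Mapping for minus-strand genes walks
the CDS intervals in descending genomic order and complements bases.
Round-tripping (`map_genome_to_cds ∘ map_cds_to_genome` = identity) is
property-tested on randomized multi-exon fixtures of both strands
against a per-base enumeration oracle. Ambiguity codes are rejected at
model-build time: the analysis assumes an unambiguous reference, and a
model whose sequence disagrees with the FASTA it was extracted from
fails construction.

In-silico digestion places the cut a configurable offset into each
recognition-site occurrence (default T^CGA for Taq1). Only fragment
lengths and site destruction are scientifically interpretable
(electrophoresis observables); the cut chemistry default is a
convention. Occurrences are scanned left-to-right and scanning resumes
after each accepted occurrence, so overlapping occurrences of
self-overlapping sites resolve deterministically.

## Pileup tallies and the background-error null

Every filter-passing aligned base over a CDS position contributes to
exactly one of five categories — A, C, G, T, ambiguous — in transcript
orientation. N calls, deletions and reference skips are ambiguous;
bases below the base-quality floor are excluded from depth entirely.
Defaults: base quality ≥ 13, mapping quality ≥ 0, duplicates and
secondary/supplementary alignments excluded. The quality floor
approximates the default behaviour of common pileup tools; base
alignment quality (BAQ) recalibration is **not** reimplemented, so
counts from BAQ-enabled pileups can differ slightly. Overlapping mate
pairs are counted independently by default (a `collapse_mate_overlap`
flag de-duplicates by read name per position).

The editing fraction at the target site is compared against the pooled
fraction of the same substitution at *all* CDS positions sharing the
site's reference base. The pool includes the query site by default —
matching the "any of the 213 C positions" formulation — with an
exclude option for a cleaner null; at realistic depths and error rates
the difference is a few parts in 10⁴ of the background. Ambiguous
calls stay in the depth denominator by default (they are one of the
five categories); a toggle removes them. The test is the two-tailed
chi-square with Yates continuity correction on the 2×2 table (site
edited/non-edited vs background edited/non-edited), clipped to zero
when |ad−bc| ≤ N/2, with p from the χ²₁ distribution.

A calibration caveat that the test suite asserts: at depth ~5000 with
a ~0.06% background, expected edited counts at the site are ~2, and
the continuity correction makes the test *conservative* — measured
null rejection is ≈ 0.016 at nominal α = 0.05. The suite therefore
checks validity (type-I error ≤ α), not equality with α, plus
agreement of the statistic with an independent contingency-table
implementation to 1e-9.

SNP exclusion takes a user-supplied list (VCF or chrom/pos TSV) and
only flags overlap; no live database access.

## Allele-specific qPCR model

Each sample is measured by a total-transcript assay and an
edited-allele-specific assay (discriminating 3′-terminal primer base).
Replicates are averaged on the Cp scale. The edited fraction is

    f̂ = (1 + E)^(Cp_total − Cp_allele)

with E = 1 assumed by default; fractions above 1 (inverted ΔCp) are
clipped with a warning rather than erroring, since noisy wells can
invert the difference. Efficiency is measured from a d-fold serial
dilution: least squares of mean Cp on step index gives cycles/step s
and E = d^(1/s) − 1 (8-fold with 3.0 cycles/step is perfect doubling;
2.8583 cycles/step gives 107%).

Specificity is characterised on pure synthetic templates: the apparent
fraction on 100% wild-type template (false-positive amplification,
default forward-model value 1.38%) and on 100% edited template
(recovery, 91%). The linear unmixing correction
(f = (obs − fp)/(recovery − fp), clipped to [0,1]) is provided but
**off by default**: uncorrected estimates are deliberately stringent
(slight underestimates), and the forward model ∘ correction is
identity at zero noise, which the tests assert. Relative expression
uses 2^−ΔΔCt against a housekeeping gene.

## Amplicon screening

Variant calls require fraction strictly greater than the reporting
threshold (default 10%) at depth ≥ 100. The comparison is done in
exact rational arithmetic (`alt_count·q > p·depth` for threshold p/q),
so a variant at exactly the threshold is never reported regardless of
floating-point representation. Classification into canonical editing
classes (A→G, C→T) operates in transcript orientation only; amplicons
derive from sense-strand RT-PCR, so antisense classes are out of
scope. The sequencing-vs-qPCR comparison reports both the mean of
per-pair relative excesses and the ratio of means, because "X% higher
on average" is ambiguous between them (on the published four-sample
table they are 43.7% and 42.1%).

## Cohort statistics

Paired condition comparisons use the Wilcoxon matched-pairs
signed-rank test: zero differences dropped, |differences| midranked,
and the exact null distribution of W⁺ computed by dynamic programming
over doubled midranks — arithmetically identical to enumerating all 2ⁿ
sign assignments, and valid under ties — for n ≤ 25 pairs; above that,
the normal approximation with the midrank variance Σrᵢ²/4 and
continuity correction. Unpaired comparisons use Mann-Whitney U with
the exact subset-sum distribution for combined n ≤ 20 and the
tie-corrected normal approximation above. Both implementations are
tested against brute-force enumeration oracles (all sign patterns /
all labelings) on small instances and against independent library
implementations on tie-free instances. The exact/approximate cutoffs
are desk-scale choices: exact beyond them is possible but unnecessary
at cohort sizes of 4-42 donors. Pearson correlation and the
pure-population extrapolation (OLS of editing on cell-type fraction,
evaluated at fraction 1.0, flagged as an extrapolation when 1.0 is
outside the observed range) delegate to standard library routines.

Published headline p-values from donor cohorts are treated as context,
not reproducible targets — the underlying donor tables are not
available — so the tests validate the statistics by oracle equivalence
and by power simulation (a five-fold hypoxia effect at n = 14 paired
donors is detected at α = 0.05 with power > 0.9).

## Synthetic data: what it emulates and what it does not

The fixture locus is **synthetic**: a deterministic generator builds a
minus-strand, 8-exon gene whose CDS reproduces the structural facts
that the analysis depends on — 843 bp (281 codons), exactly 213
cytosine positions, codon 46 = CGA inside the region's only TCGA so
that the C>T edit at c.136 is nonsense and destroys the Taq1 site, and
the edit site in exon 2 — with all other bases drawn from a seeded
RNG. Companion amplicons (285 bp cDNA, 233 bp gDNA) place that site so
digestion yields 159+126 and 131+102 bp fragments. No RefSeq sequence
is bundled; the real gene can be supplied as BED12 + FASTA.

Read simulation draws fixed-length (default 50 bp), single-end,
fully-matching reads uniformly over the locus at a target mean
coverage; each read descends from a molecule edited at a covered site
with probability f, then i.i.d. per-base errors at rate ε land
uniformly on the three wrong bases (ε/3 each — the aggregate, not the
spectrum, is constrained by observation, so uniformity is a documented
modeling choice). A multinomial shortcut (`simulate_tally`) generates
per-position tallies with the same marginal distribution; expected
site fraction f(1−ε) + (1−f)ε/3. Truth records store every simulated
molecule count, and estimator tests compare against truth, never
against the outputs being tested. Not modeled: realistic base-quality
profiles, PCR duplicates, paired ends, splice-aware read placement,
alignment artifacts. Passing tests therefore demonstrate correctness
of the counting, coordinate and testing machinery — not robustness to
real-world alignment pathology.

The qPCR simulator computes Cp = log₍₁₊E₎(C/template) + N(0, σ²) with
the allele assay seeing template·(f·recovery + (1−f)·fp); defaults
E = 1, σ = 0.1 cycles, fp = 1.38%, recovery = 91% (the forward-model
values of the characterised assay). The cohort generator gives each
donor a log-normal baseline (median 2%, log-SD 0.6), a log-normal
hypoxia multiplier (median 5, applied to a day profile peaking on day
2), a normoxia day profile peaking at days 5-7 (~5-fold), Beta(2.2,
5.8) CD14⁺ fractions (mean ≈ 27%), and multiplicative log-normal
measurement noise (log-SD 0.25). The CD14-editing link strength (2.0)
was calibrated so the induced uncultured-cohort Pearson correlation
matches the reported weak positive correlation (r ≈ 0.36 observed;
≈ 0.38 induced). Donor noise magnitudes are invented — the source data
constrain only ranges — and are labeled as such.

## Numerical and interface conventions

Genomic coordinates are 0-based half-open internally; all formatted
output (tally TSV, VCF-style positions) is 1-based. Seeds are
mandatory for every stochastic generator. Undefined statistics (zero
depth, zero marginal, zero variance, all-zero differences) raise typed
exceptions rather than returning NaN. Problem sizes used by the
default test run and the acceptance script (depth 5000 pileups, ≤ 10⁴
reads for oracle equivalence, 2000-replicate null calibration,
200-replicate power studies) were chosen as the smallest sizes at
which the asserted tolerances are meaningful.

## Known limitations

* BAQ-style quality recalibration is approximated by a base-quality
  floor; counts can differ from BAQ-enabled pileup tools on real data.
* No transcriptome-wide editing discovery, hyper-editing rescue, indel
  calling, UMI handling or isoform resolution.
* The ΔCp estimator assumes equal amplification efficiency in both
  assays; a shared measured E can be supplied, but per-assay E is not
  modeled.
* Exact tests enumerate; beyond the cutoffs the normal approximation
  is used even when ties are heavy, where midrank corrections are
  asymptotic.
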