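# Methods

`neuraxprot` implements the downstream quantitative workflow of a
region-resolved DIA-MS study of the mouse pain neuraxis: seven tissues —
sciatic nerve (SN), dorsal root ganglia (DRG), spinal cord (SC), and four
brain regions (anterior cingulate cortex ACC, amygdala AMY, prefrontal
cortex PFC, cerebellum CER) — profiled in two conditions (Sham control and
SNI, spared nerve injury, a surgical neuropathic-pain model) with three
replicates per tissue and condition, each replicate a pool of four animals.
The pipeline starts from a long-format peptide quantification table as
produced by DIA search software and ends with tissue proteomes, PNS/SC
enrichment calls, regulation statistics, QC diagnostics and list-overlap
reports.

## Data model and filtering

A measurement is one positive, linear-scale peptide intensity in one
(tissue, condition, replicate) cell; non-detection is an absent row, and
zero or negative intensities are dropped at load and counted. Intensities
stay linear throughout; log2 transforms are applied only inside the
operations that are defined on the log scale. Before any tissue-level
analysis, measurements are restricted to reviewed UniProt identifiers and
keratin contamination is removed (via an annotation flag, or a `Krt*`
gene-prefix convenience rule when no flag column exists). Unannotated
proteins are dropped with a warning by default so that public reports with
mixed identifier spaces still load.

## Rollup, detection and tissue proteomes

Protein intensity per replicate is the arithmetic mean of its linear
peptide intensities in that cell. A protein is detected in a
tissue/condition when each of the three replicates contains at least one of
its peptide observations; the reading is protein-level (any peptide per
replicate), with a `same_peptide=True` switch for the stricter
one-peptide-in-all-replicates interpretation. The tissue proteome lists all
detected proteins — single-peptide identifications included, but flagged —
with the cross-replicate mean, sample standard deviation (n−1) and peptide
count. The cross-replicate mean is computed over replicate means by
default; `mean_over="pooled"` averages all peptide observations instead
(the two differ when peptide coverage is unbalanced across replicates).

## Enrichment classification

PNS- (SN, DRG) and SC-enriched proteins are defined against the four brain
regions by a two-criterion subtractive procedure. Criterion A: the protein
passes detection in the target tissue but in none of the brain regions.
Criterion B: the ratio of the target-tissue mean to the *maximum*
brain-region mean strictly exceeds the fold threshold (default 10, one
order of magnitude) **and** a one-tailed Welch's t-test of the target
replicates against the max-region replicates gives p < 0.05. Only brain
regions where the protein passes full detection contribute to the maximum;
ties break to the first region in the fixed order ACC < AMY < PFC < CER.
The Welch test runs on linear intensities (abundance, not log abundance;
`log_scale=True` switches). With three replicates per group the test is
fragile when variances vanish: a pair with two zero variances falls back to
a fold-only decision with a logged warning; a group with fewer than two
replicate values makes the protein untestable.

A secondary filter re-screens enriched proteins against a deeper reference
analysis of the brain (e.g. one quantified against an in-silico brain
spectral library): any protein with *any* observation in a secondary brain
tissue — partial one- or two-replicate coverage counts as detected here,
deliberately stricter than the primary criterion — is removed unless it
again exceeds the fold threshold over the secondary maximum with Welch
p < alpha.

Tissue preference: an enriched protein is SN- or DRG-specific when it is
enriched in that tissue and not even detected in the other PNS tissue's
proteome; otherwise shared. This operationalization (detection in the other
tissue, not enrichment) is a documented package choice where the underlying
definition is open.

## Regulation statistics

For each peptide quantified in all three control and all three case
replicates of a tissue, three replicate-paired ratios log2(case_r /
control_r) are formed; peptides missing any of the six cells contribute
nothing, so proteins absent from a condition yield no record at all. A
protein's effect estimate is the mean of all its peptide-pair ratios, and
its p-value a two-sided one-sample t-test of those pooled ratios against
zero (3 × n_peptides values). Pooling keeps single-peptide proteins
testable (three values), consistent with reporting single-peptide hits as
"low confidence"; `sample_unit="pair_means"` tests the three per-pair
protein means instead. Two-sided testing is used because both up- and
down-regulation are reported. Degenerate ratio sets: all-zero ratios give
p = 1 (no evidence of change); a non-zero constant gives an undefined p and
excludes the protein from the multiple-testing family rather than
fabricating an infinite t statistic.

P-values are adjusted per tissue with the Benjamini–Hochberg step-up
procedure over the reviewed, non-contaminant proteins with defined p;
`regulated` means q strictly below 0.05, and `low_confidence` marks
regulated calls resting on a single peptide. Regulated sets from several
pain models (e.g. SNI vs CFA) are compared by an exclusive-region partition
that carries each model's direction label (up/down by the sign of the mean
log2 fold change).

## Reproducibility diagnostics

Per-replicate protein means are assembled into a proteins × samples matrix
with explicit missing values and a transform-state flag. Pearson
correlations between samples are pairwise-complete (each pair uses its own
shared-row set; pairs with fewer than two shared rows are undefined with a
warning). For clustering, rows are log2-transformed and z-scored (mean 0,
sample sd 1 over non-missing entries); constant rows z-score to all zeros
and are flagged rather than dropped, keeping the row universe stable
between correlation and clustering, while rows with a single observation
are dropped (sd undefined). Hierarchical clustering uses Euclidean distance
with average (UPGMA) linkage over samples and over proteins
(complete-case rows only, the standard heatmap-tool behaviour); flat
protein clusters are cut at distance 3.4, a visualization threshold for
grouping co-expressed proteins. Determinism: labels are sorted
lexicographically before linkage, which makes the dendrogram invariant to
input permutation without re-implementing tie-breaking inside the
agglomeration. An optional kernel-density plot (Gaussian kernel, Silverman
bandwidth) summarises sample intensity distributions.

## Overlap reports

External identifier lists (pain gene databases, transcriptome lists, atlas
presence lists) are converted to the package's accession space through a
user-supplied two-column mapping table — no network access; conversion
losses are counted, and raw identifiers mapping to several accessions keep
all targets (union semantics, conservative for overlap claims). Reports
give intersection counts, both directional percentages (full precision in
tables; round-half-up integers in display text), exclusive Venn regions for
two or three lists (region counts sum to the union size), and atlas
subtraction (enriched minus atlas-present, yielding candidates whose
enrichment may extend to species the atlas does not cover).

## Synthetic study generator

`simulate_study` emulates the study design so every stage has a closed
testing loop. Intensity model (all factors multiplicative, linear scale):

    I(p, j, t, c, r) = A_p · E_{p,t} · G_{p,c,t} · F_j · N

* `A_p` — protein base abundance, lognormal with log2 mean 20 (≈10⁶
  arbitrary units, typical of DIA protein intensities) and log2 sd 2
  (spanning ~4 orders of magnitude, as real proteomes do);
* `E_{p,t}` — planted tissue-enrichment fold for target tissues (must be
  > 1 and never a brain tissue; brain regions are always 1 so the planted
  fold equals the true fold over the maximum brain mean);
* `G` — 2^(log2 effect) in the case condition for planted (protein,
  tissue) pairs;
* `F_j` — peptide response factor, lognormal with log2 sd 1, fixed per
  peptide across all cells (peptides of one protein differ in ionization
  efficiency by about an order of magnitude);
* `N` — replicate noise, mean-1 lognormal with a configured CV (default
  0.1, converted to log-space sd via σ² = ln(1 + CV²)); pooling of four
  animals per replicate is folded into this single CV rather than modelled
  as latent animals, since the pipeline never sees animal-level data.

Missingness is random dropout plus an abundance-dependent logistic term
rising as log2 intensity falls below a midpoint — low-abundance peptides go
missing first, as in real DIA data. Contaminant (Krt-gene) and unreviewed
proteins are appended from the tail of the protein index so planted sets
stay disjoint from them. Randomness is counter-based (numpy Philox keyed by
seed and protein index with a fixed draw order), so outputs are
byte-identical per (config, seed) and single proteins can be regenerated
without simulating the rest.

What the generator does **not** emulate: peptide sequences, charge states
and spectra; between-run normalization artifacts; correlated peptide
interference; batch effects; shared-peptide (razor protein) ambiguity.
Passing tests therefore demonstrate correctness of the statistics and
decision rules under the declared noise model, not robustness to every
pathology of real DIA data.

## Verification sizes and tolerances

The statistical primitives (Welch t, one-sample t, BH) are checked against
independent textbook implementations to 1e-10 on 1,000 random instances,
and worked micro-examples are asserted exactly. False-discovery control is
verified on global-null simulations (1,000 proteins × 3 peptides, CV 0.1,
20 seeds; mean realized false-discovery proportion compared to the nominal
5% with a two-sigma binomial Monte-Carlo allowance). Parameter recovery
uses 20 seeds each for a planted log2 effect of 1.0 (mean absolute error
≤ 0.15, detection power ≥ 0.8) and planted 20- vs 2-fold enrichments
(sensitivity ≥ 0.9, false-call rate ≤ 0.05). Noise-free runs (CV 0, no
dropout) must reproduce detection sets and planted effects exactly.
Two-tissue clustering recovery (CV 0.05, 20 planted tissue markers) must
produce tissue-pure clades in ≥ 19 of 20 seeds. These problem sizes keep
the default suite to well under a minute per check while leaving the
Monte-Carlo tolerances meaningful.

## Known limitations

* No between-run normalization: upstream software is assumed to have
  produced comparable intensities across runs.
* The Welch test with n = 3 per group has little power and unstable
  degrees of freedom; the enrichment procedure leans on the 10-fold
  criterion as the primary filter, as the study design intends.
* Shared peptides are attributed to whichever protein identifier the
  report assigns; no razor-protein logic.
* Identifier mapping is consumed as data; the package never calls external
  services.
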