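# Methods

## Scope and data model

The package covers the cohort-analysis portion of a neoantigen profiling
study: it begins after somatic variant calling and HLA typing, and before
any wet-lab validation. Inputs are plain text: a MAF-like variant TSV
(patient, gene, optional ref/alt nucleotide, optional protein change in
compact `T96S` notation, class `missense`/`indel`), a clinical TSV (sex,
age, TNM), an HLA genotype TSV (two-field class-I alleles, normalised to
`A*11:01` form), protein FASTA keyed by gene, an optional cancer-gene list,
and an optional precomputed peptide–allele affinity TSV.

Records are validated on construction. Variants may lack nucleotide fields
(protein-only annotation) or protein fields (indels); operations that need
the missing piece skip the record and report how many they skipped, while
counting operations use every record. TNM strings are parsed
case-insensitively for the T component because clinical tables are
inconsistent in case (`T4Bn3aM0` → `T4b`). HLA genotypes use set semantics:
carrier frequency counts patients, not chromosomes, so homozygous loci
collapse harmlessly.

## The packaged reference cohort

Two published tables from a 32-patient gastric-cancer exome study travel
with the package: the per-patient table (sex, age, TNM, missense/indel/
neoantigen counts) and the driver-mutation table (25 missense mutations in
PIK3CA, FAT4, BRCA2, GNAQ, LRP1B and PREX2, with carrier HLA alleles,
per-mutation neoantigen counts and ICGC occurrence counts). The tables are
the quantitative anchor: every summary statistic and association test on
them is exactly reproducible, and the test suite freezes those values.
Where the prose summaries around the original tables disagree with the
tables themselves (column totals, the indel median, T-stage counts), the
tables are taken as ground truth; in particular the indel column's median
is 13, and the package reports 13. The ICGC column is carried as fixture
data only and never recomputed.

## Peptide enumeration

For a missense variant the mutant protein is built by substituting one
residue, after checking that the annotated reference residue matches the
FASTA (a mismatch is a hard error — it signals transcript drift, not a
recoverable condition). Candidates are all windows of length 8–11 that lie
fully inside the protein and cover the mutated position, in deterministic
order (ascending length, then start). Windows truncated at the termini are
dropped, not padded: class-I ligands are contiguous peptides. The count per
length L follows the closed form min(p, N−L+1) − max(1, p−L+1) + 1, checked
exhaustively against brute force for all protein lengths up to 50.
Duplicate peptide sequences arising from sequence repeats are collapsed
within one mutation but kept across distinct mutations, since burden is
counted per (peptide, allele) pair per patient. Indels and stop-gains are
excluded from enumeration; they are counted but never scored.

## Binding predictor contract

Affinity prediction is a contract: `score(peptide, allele) → IC50 (nM)`
plus a determinism flag and a declared allele coverage. Two
implementations:

* **Table predictor** — a lookup over precomputed affinity rows (e.g. real
  neural-predictor output). A missing pair raises a not-covered error,
  never a silent default; conflicting duplicate rows fail at load.
* **Mock predictor** — deterministic and explicitly non-biological, for
  tests and synthetic cohorts. Per allele it draws anchor-position weights
  (position 2 and the C-terminus) from a seeded generator, adds a
  hash-derived peptide–allele perturbation, and maps the sum to
  log10 IC50 ≈ 2.35 ± spread, clipped to [1, 50 000] nM. Roughly 40 % of
  random pairs fall below 100 nM and 40 % above 500 nM, so both thresholds
  are exercised. Identical (seed, peptide, allele) always yields the same
  score.

Thresholds: a pair is called a neoantigen at IC50 ≤ 500 nM (the
conventional binder cutoff; configurable, since the reference study states
only the strong cutoff) and a strong binder at IC50 < 100 nM. Calls are
sorted by IC50 with deterministic tie-breaks. Lowering the weak threshold
can only remove calls, and strong calls are a subset of neoantigen calls at
every setting — both properties are tested.

## Mutation spectrum

Substitutions are collapsed onto the pyrimidine strand (G>T → C>A,
A>G → T>C, …), yielding the six classes; transitions are C>T and T>C. The
twelve ordered base pairs map two-to-one onto the classes. The spectrum is
computed over missense records with nucleotide annotation only; an
all-skipped input yields an explicit undefined state rather than NaN
arithmetic. No trinucleotide context or signature decomposition is
attempted.

## Cohort summaries and recurrence

TMB is missense count divided by the interrogated exome size, default
30 Mb — the convention under which the reference cohort's median of 138
missense mutations equals 4.6 mutations/Mb. The default is configurable
because capture kits differ. Hypermutators are patients with TMB > 40/Mb.
Gene recurrence counts distinct patients (a gene hit eight times in one
patient is one carrier) with a default threshold of three patients; census
intersection matches symbols exactly but case-insensitively. Fractions are
kept at full precision internally; a formatting layer rounds half-up for
reports (9/32 → 28.13 %, 15/32 → 46.9 %).

## Association statistics

The rank-sum convention is fixed and recorded on every result: midranks for
ties; U statistic for group A; tie-corrected variance
(n_a·n_b/12)·[(n+1) − Σ(t³−t)/(n(n−1))]; z without continuity correction;
one-sided normal-tail p-value. This exact convention reproduces all four of
the reference cohort's published subgroup p-values (0.0202, 0.0294, 0.0795,
0.1525); exact-permutation and continuity-corrected variants are available
behind flags and do not. The age split is ≤ 45 vs > 45 (the reference
cohort's "below 45, n = 4" group includes a patient aged exactly 45, and
only the inclusive split reproduces p = 0.1525). Group comparisons with
fewer than two members on either side are skipped with a warning.
No multiple-testing correction is applied by default — raw p-values are
reported, matching the source convention — but a Benjamini–Hochberg helper
exists.

Numerical behaviour of the normal approximation at small samples: against
an exhaustive permutation oracle the worst-case absolute error is 0.167
when the smaller group has 2 members, shrinking to 0.035 at 6 vs 6 (derived
by enumerating every achievable U, tie-free). The acceptance tests assert
the implementation's exact mode against an independent enumeration oracle
and the normal mode at those derived bounds. The one-sided test's null
rejection rate at α = 0.05 is 0.050 ± 0.01 over 10 000 seeded simulations
with groups of 20.

The missense-vs-neoantigen relationship is a single OLS fit
(scipy.stats.linregress); R² equals the squared Pearson correlation and is
0.8845 on the reference cohort.

## Synthetic cohort generator

The generator emulates the study's statistical structure so every stage is
testable without external data. Per-patient missense counts are log-normal
(default log-mean log 138 ≈ 4.93; log-sd 0.78, the empirical log-sd of the
reference cohort's 30 non-hypermutator patients) with a hypermutator
mixture (probability 2/32, scale ×10) reproducing the long right tail a
single log-normal fits poorly. Substitution classes are i.i.d. from the
six-class probabilities (defaults: the reference spectrum, C>A 32.18 % …
T>A 5.89 %), presented on either strand with equal probability. Indel
counts are Poisson with mean 0.087 × missense (the reference ratio
658/7594). Genes are drawn from a Zipf-like pool (600 genes, exponent 0.9)
over randomly generated proteins of 120–600 residues, giving MUC4-style
recurrence at the top of the table. HLA alleles are independent carrier
draws from a pool whose head matches the reference carrier frequencies
(A*11:01 0.469, C*01:02 0.375, …), with at least one allele guaranteed.
Stage, sex and age follow the reference composition (2/7/5/18 across
T1a/T2/T4a/T4b; 11/32 female; ages 38–80). A per-stage latent factor
(default T1a 2.0, T4b 0.8, mirroring the early-stage excess) scales
predicted affinities per patient via a wrapper predictor, so stage effects
propagate to neoantigen counts without touching the scorer.

Identical configs (including seed) give byte-identical output files. The
parameter-recovery suite regenerates a cohort, reruns the full pipeline,
and checks median burden (3 SEs of a median on the log scale), spectrum
and carrier frequencies (3 binomial SEs), and R² > 0.5 between missense
and neoantigen counts when the stage effect is constant. Recovery runs
enumerate 9-mers only, keeping the predictor loop proportionate to a check;
cohorts of 8–32 patients are used throughout the tests, and the
study-scale 32-patient default (~7 000 missense) for spectrum recovery.

What passing these tests shows: the machinery — parsing, enumeration,
thresholding, counting, testing — is correct under the stated conventions.
What it does not show: anything about real binding biology (the mock
predictor is noise with anchors), real mutation processes (no context
dependence, no linkage), or the reproducibility of the reference study's
sequence-level results (its raw variant calls were never deposited, so the
232-gene and 54-gene lists and the printed spectrum percentages serve as
generator defaults, not as recomputable targets).

## Known limitations

* Per-patient neoantigen counts are reproducible only from the packaged
  summary table, not from sequence: the original predictor's exact
  thresholds and version are unknown, and the weak-binder cutoff (500 nM)
  is a convention, not a published parameter of the study.
* The rank-sum normal approximation is anti-conservative in the extreme
  tails at group sizes of 2–3; the exact mode exists for such cases.
* Recurrence fractions use missense carriers only; whether indels should
  count toward occurrence is left to the caller (they do not here).
* The generator draws mutations independently; it cannot emulate clonal
  structure, signature mixtures, or allele-linkage effects.
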