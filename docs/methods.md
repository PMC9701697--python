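# Methods

## The screening model

The screen treats kinship detection as a diagnostic test on an integer
statistic. For a pair of STR profiles, each locus contributes a shared-allele
count: the size of the multiset intersection of the two genotypes (0, 1, or
2). Allele identity is exact label equality on the repeat-count string, so a
9.3 microvariant never matches a 9 and homozygotes (stored as two explicit
copies) can contribute two matches. Alleles identical by state may or may
not be identical by descent; the screen deliberately ignores the
distinction, which is what frees it from population allele-frequency data.

Per-pair scores aggregate the locus counts:

- **Autosomal OAM** — number of loci with *exactly one* shared allele.
- **Autosomal TAM** — number of loci with *two* shared alleles.
  The categories are exclusive, so OAM + TAM ≤ panel size. Exclusivity is
  the only convention consistent with the reference analyses: the
  reconstructed unrelated sibling distributions reproduce the published
  group means (e.g. 7.48 OAM / 0.80 TAM over 15 loci) only when full-match
  loci are not double-counted in OAM.
- **X OAM** — number of loci with *at least one* shared allele. Males are
  hemizygous, so a full match can be a single allele; the at-least-one rule
  is the only one under which the obligate-sharing configurations reach the
  panel ceiling (sisters share their father's X at every locus → 12 of 12;
  likewise paternal grandmother → granddaughter), as the reference results
  report.

Loci are scored independently. The Argus X-12 markers physically sit in
four linkage groups, but the method matches each marker individually — a
deliberate choice to stay agnostic to population-specific linkage
disequilibrium — and the simulator mirrors it with free recombination.

## ROC construction and cut-off selection

Candidate cutoffs follow the SPSS convention: sorted distinct observed
scores v₁ < … < v_k map to [v₁−1, (v₁+v₂)/2, …, (v_{k−1}+v_k)/2, v_k+1],
with sensitivity and 1−specificity computed as the fraction of each group at
or above the cutoff. AUC is the trapezoidal area, which for this
construction equals the normalised Mann–Whitney U with ties counted half
(cross-checked against `scipy.stats.mannwhitneyu` in the tests).

Two selection criteria are implemented:

- `youden`: maximise J = sensitivity − (1 − specificity);
- `closest_topleft`: minimise (1 − sensitivity)² + (1 − specificity)²,
  the Euclidean distance to the ideal corner.

The reference study describes its selections as Youden-based, but in three
of its ten analyses the chosen cutoff is *not* the J-maximiser (it picks
8.5 where J peaks at 9.5, 5.5 vs 6.5, and 9.5 vs 11.5). The
closest-to-corner rule reproduces **all ten** published selections exactly,
including the one exact tie (7.5 vs 8.5, where the published choice is the
larger cutoff). The reproduction pipeline therefore uses
`closest_topleft` as the published rule, with ties resolved to the largest
cutoff — which also favours specificity, the right bias for a
screen-then-confirm workflow. Both criteria are exposed; the evaluate
command takes `--criterion`.

The selected half-integer cutoff is ceiled to the integer AMCOS (scores are
integers, so "score ≥ c" and "score ≥ ⌈c⌉" classify identically for
interior cutoffs). Endpoint cutoffs (min−1, max+1) are eligible but lose
ties against interior cutoffs.

## Diagnostic metrics and intervals

From the 2×2 table at the AMCOS (positive = score ≥ AMCOS): sensitivity
tp/(tp+fn), specificity tn/(fp+tn), PPV tp/(tp+fp), NPV tn/(tn+fn),
accuracy (tp+tn)/N, LR+ = se/(1−sp), LR− = (1−se)/sp. Estimates are kept as
exact integer fractions; any metric with a zero denominator — or an infinite
LR+ when specificity is 1 — is reported as an explicit undefined marker,
never coerced to 0 or ∞.

Interval choices, each isolated behind one function so it can be swapped:

- **Sensitivity / specificity / accuracy:** Clopper–Pearson exact
  (`statsmodels` "beta"), verified in tests against brute-force binomial
  tail inversion for all n ≤ 30 and against the reference anchors
  (23/25 → 73.97–99.02%; 25/25 → 86.28–100%; 48/50 → 86.29–99.51%).
- **PPV / NPV:** Wilson score on the realised fraction. The reference
  study's tool is not identifiable from its text; Wilson reproduces its
  25/27 anchor (76.79–97.93%) to within 0.2 percentage points and has good
  small-sample coverage (checked by simulation at n = 30).
- **LR+ / LR−:** the standard log-method,
  exp(ln LR ± z·SE) with SE²(ln LR+) = 1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)
  and the analogous form for LR−. This reproduces the reference LR+
  intervals exactly (e.g. 1.86 with 0.89–3.86 from tp 13, fp 7, fn 12,
  tn 18).

No prevalence adjustment is applied to predictive values — they are reported
at the sample's composition, as in the reference analyses — and no
multiple-testing correction is performed.

## The significance gate

Groups proceed to ROC analysis only if related and unrelated scores differ
at p < 0.05. Because the source does not state which of "t-test or
Mann–Whitney" fired where, the gate screens each group for normality with
Shapiro–Wilk at α = 0.05: both normal → Welch's unequal-variance t
(safer than pooled t under unequal spreads); otherwise Mann–Whitney U
(asymptotic, tie-corrected). The choice is always recorded in output;
downstream selection does not depend on it. Constant identical groups short
circuit to p = 1. Under the null the gate fires at ≈ 5% (checked over 2 000
replicates).

## The pedigree simulator

`simulate_pairs` builds related pairs by explicit pedigree construction —
two shared founder parents for sibling types; a three-generation chain for
grandparent types, with the lineage (paternal/maternal ×
grandfather/grandmother) and grandchild sex configurable — and unrelated
pairs as fresh founders of the sexes the hypothesis requires. Founders draw
alleles locus-wise from a frequency table (two independent draws, one for
males at X loci). Transmission is uniform over the parent's alleles,
independent per locus; a father passes his single X to daughters
deterministically and nothing to sons (requesting that transmission is a
structural error). Founder alleles carry unique origin tags, so per-locus
IBD counts are exact and the invariant IBD ≤ IBS holds by construction.

Defaults emulate the reference study's conditions: mutation rate 0 (so the
obligate-sharing X invariants are exact); an optional ±1-repeat single-step
model is available because forensic STR mutations are overwhelmingly
single-step, but no reference value depends on it. The synthetic frequency
generator draws symmetric-Dirichlet frequencies (default 8 alleles per
locus, concentration 1 — heterozygosities in the range typical of forensic
STR panels). What the simulator does *not* model: silent/null alleles,
genotyping error, population substructure (the reference study explicitly
omits θ correction), or X linkage groups. Passing simulator-based tests
therefore demonstrates correctness of the inheritance and scoring logic,
not performance on any real population, where allele frequencies, typing
artefacts, and substructure will move the score distributions.

## Reconstruction of the reference analyses

The ten published coordinate tables list every (cutoff, sensitivity,
1−specificity) triple. Since interior cutoffs are midpoints of consecutive
observed integer scores, the observed scores unroll exactly from the cutoff
column (v₁ = c₁+1, v_{i+1} = 2c_{i+1} − v_i), and each group's count at each
score is n·(fraction ≥ previous cutoff − fraction ≥ next cutoff). Group
sizes are inferred as the smallest n ≤ 100 under which every printed
3-decimal fraction is k/n for an integer k, cross-checked against the study
design (25/25 opposite-sex siblings, 20/20 same-sex siblings; the
grandparent X analyses split 7 paternal / 13 maternal).

Reconstruction is exact everywhere except a handful of verified print
defects, which are recorded per-analysis in the fixture metadata and
reported as "known print defect" (never silently matched) by
`amcos reproduce`:

- the autosomal grandparent table's 1−specificity 0.350 at cutoff 9.5 fits
  no group size ≤ 100 (every other cell fits n = 26; 9/26 = 0.346), and the
  same analysis's summary column (sensitivity 85.20%, accuracy 78.85%) is
  inconsistent with its own coordinates (23/26 = 88.5% at the cutoff);
- the sibling TAM related mean: coordinates force 3.96, caption prints 3.92;
- the brother–brother TAM AUC is exactly 399/400 = 99.75%, printed as
  99.77% in one place and 99.7% in another;
- three standard deviations (2.075 duplicated across two analyses; 0.040
  and 0.326 with dropped digits).

Comparison precision follows each printed value: half a printed unit for
AUCs, cutoffs, and metrics; one printed unit for means/SDs (the source
shows occasional truncation rather than rounding). Internal values are
exact rationals; AUC rounding to printed precision uses ties-to-even
(99.25 → 99.2, matching the source's own print of its half-way value).

## Numerical and interface choices

- Allele labels are never coerced to numbers anywhere in the pipeline.
- Genotype files are long-format (one row per sample × marker), the only
  dialect that represents mixed-ploidy X data without sentinel values; a
  blank Allele2 at an autosomal locus is an error, not an implied
  homozygote.
- Missing loci are hard errors by default; permissive mode drops the locus
  for that pair and reports `loci_used`, because scores over unequal locus
  counts live on different scales.
- Scoring is symmetric in the pair order; cutoff selection is invariant
  under duplicating every score.
- Tests run the simulator at reduced but statistically adequate sizes
  (≈ 10⁴ locus-draws for the Mendelian ratio checks, tolerance ±2
  percentage points, seeds fixed).

## Known limitations

The ten reference analyses rest on small samples (7–26 pairs per group), so
the packaged cut-offs are proof-of-concept values, not validated operational
thresholds. The screen is IBS-only: mutations, null alleles, and chance
sharing in low-diversity populations all shift scores, and nothing here
replaces LR-based confirmation. No Y-STR, amelogenin, mitochondrial, or
linked-marker support is included.
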