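# Methods

## Study design being modelled

A single extended family segregating a strong phenotype (unprovoked venous
thromboembolism) under apparent autosomal-dominant transmission. Whole-exome
sequencing is applied to a subset of members — a few affected relatives
chosen to be as genealogically distant as possible, plus unaffected
relatives chosen to be genetically close to them — and candidate variants
are whittled down by a filtering cascade, then validated by genotyping the
whole pedigree (co-segregation), screening external cohorts, and comparing
intermediate plasma phenotypes between carriers and non-carriers.

## Kinship and subject selection

Kinship is Wright's coefficient φ(i,j), the probability that one allele
drawn from each of i and j is identical by descent, computed by the
standard pedigree recursion with founders assumed unrelated and non-inbred
(inbred descendants are handled by the recursion itself; φ(i,i) =
½(1 + φ(father, mother))). The recursion always descends through the member
of greater generation depth, which guarantees termination and correctness
because an ancestor's depth is strictly smaller than its descendant's.

"Most distant affected" is operationalised as the k-subset of affected
members minimising the sum of pairwise kinship coefficients, and
"genetically close controls" as the m-subset of unaffected members
maximising summed kinship to the chosen cases. Both searches are exhaustive
over all subsets (the family has 5 affected / 10 unaffected; enumeration is
trivial), and ties break deterministically to the lexicographically first
sorted id set. These optimisation criteria are this package's
formalisation of the study design's verbal description; no algorithm was
published for the original choice.

## Filtering cascade

Filters run in discovery order: (1) carried by every sequenced case,
(2) carried by no sequenced control, (3) likely-functional consequence
class {stop gain, stop loss, frameshift indel, nonsynonymous, splicing},
(4) maximum reference-panel allele frequency < 0.001, (5) predicted
deleterious — SIFT deleterious, PolyPhen probably damaging, CADD PHRED
≥ 20, conjunctive but individually toggleable since the original composite
rule was not fully specified. Filters 3–5 are pure per-variant predicates
and commute (asserted by permutation in the tests); the order is fixed
only so the audit report's stage counts are comparable across runs.

Policy choices where the original workflow is silent:

- Missing case genotype (default `strict`): a variant whose sharing cannot
  be confirmed is dropped; a missing control genotype never excludes a
  variant (carriage cannot be confirmed). `permissive` ignores missing
  case calls instead.
- Variants unobserved in every panel pass the rarity filter: absence from
  reference catalogues is expected for a private allele and must not
  exclude it. A recorded frequency of 0 is distinct from absence and also
  passes.
- Unknown predictions pass (`keep`) or fail (`drop`) the deleteriousness
  criteria wholesale; default `keep`, conservative against discarding an
  unscored causal allele.

Heterozygous and homozygous-alternate genotypes both count as carriage
throughout (dominant model). Genotypes are unphased dosages; phase is
dropped on read.

## Co-segregation

For each candidate, members with known affection status and a non-missing
genotype are classified carrier/non-carrier; `cosegregates` requires a
non-empty case group, all cases carriers, and zero carrier controls.
Discordant members (non-carrier cases, carrier controls) are listed by id.
No formal segregation statistic (e.g. a (½)ⁿ Bayes factor) is computed:
the design's decision rule is the boolean pattern, and a statistic would
be an extension rather than a reproduction. Ranking of candidates orders
co-segregating ones first, then by case-minus-control carrier-rate
contrast, then id.

## Cohort screening and panel aggregation

Cohort screening is a carrier tally per group with missing genotypes
removed from denominators. Panel aggregation sums alternate-allele counts
and individual counts across panels and reports AF = alt alleles /
(2 × individuals) — a diploid denominator, since the aggregated resources
report genetically independent individuals. The bundled reference roster
totals 345,939 individuals with 2 alternate alleles (both in gnomAD),
giving AF = 2/691,878 ≈ 2.89 × 10⁻⁶; the per-panel split of the total is a
synthetic allocation across the five named projects (the true split is not
machine-readable) and is labelled as such in the code.

## Plasma statistics

Group summaries report mean, sample SD (n−1) and SEM = SD/√n; "±" values
in the bundled table's source are SEMs (recomputing from the raw values
reproduces the printed 1.9/1.2/0.7 at one-decimal rounding). SD and SEM
are undefined and reported as missing for n = 1.

The Mann–Whitney U statistic is computed from mid-rank sums. When
C(n₁+n₂, n₁) ≤ 10⁶ the two-sided p-value is exact: the probability, over
all equally likely assignments of the pooled observed values to groups of
the observed sizes, of |U − n₁n₂/2| at least as large as observed. Because
ties are enumerated as they stand, the null distribution is tie-correct by
construction, and it is symmetric about n₁n₂/2 (reversing the value order
maps U to n₁n₂ − U), so this definition coincides with tail doubling
capped at 1. Larger problems fall back to the normal approximation with
tie-corrected variance and a 0.5 continuity correction, and the result is
flagged `normal_approx`. At the family's 3-vs-7 group sizes with complete
separation the exact two-sided p is 2/120 ≈ 0.0167 — the minimum
attainable — which is what the package reports; coarser printed values in
the source summaries reflect a different (unstated) convention and are not
reproduced. Parameters with fewer than 2 subjects in a group are flagged
`untestable`.

## Synthetic data generator

What it emulates: a deterministic 15-member, 3-generation pedigree with 5
affected spanning two generations (index case, affected mother, maternal
uncle and aunt, affected cousin); Mendelian gene dropping of independent
bi-allelic background variants from Hardy–Weinberg founders; one causal
variant introduced as a single copy in the earliest founder ancestral to
the affected members and re-dropped (bounded at 10,000 attempts) until at
least 3 carriers span at least 2 generations; affection status then
re-derived as Bernoulli(penetrance) for carriers and
Bernoulli(phenocopy rate) for non-carriers, so at the default (1, 0) the
affected set equals the carrier set. Plasma values are Normal draws per
member from group moments (floored at 0), with SDs back-computed from the
published SEMs for f-TFPI, PAI-1, ECLT and thrombomodulin; uPA, which
showed no group difference, uses near-identical moments for both groups
(means 1.2 vs 1.1 ng/mL, SDs 0.4/0.35 — a realistic no-effect filler,
since no raw values are published).

Key defaults and why:

- `n_background_variants = 20,000`: order of magnitude of a per-family
  exome variant load entering a sharing-based cascade.
- AF spectrum Beta(0.2, 2) truncated to [10⁻⁵, 0.5]: strong rare-variant
  excess typical of site-frequency spectra; truncation avoids degenerate
  fixed/absent sites.
- `functional_fraction = 0.094`: fraction of case-shared, control-absent
  variants in likely-functional classes, calibrated to the ~108/1,153
  proportion of the emulated cascade.
- `rare_fraction_of_functional = 0.02`: probability that a functional
  variant draws a concordant deleterious prediction profile, mirroring the
  few-in-a-hundred survivors of the frequency+prediction step.
- Panel AFs are the true simulated AF times log-normal noise (σ = 0.2),
  since reference panels estimate but do not equal a family's source
  population frequency; 5% of sub-1‰ variants are additionally unobserved
  in a given panel.
- Predictions for "non-deleterious" variants draw CADD < 20, so the
  deleterious-profile fraction is exactly the configured rate.

What it does not model — hence what passing tests do not show about real
data: linkage disequilibrium and shared haplotypes among background
variants (sites are dropped independently), sequencing/genotyping error,
X-linked inheritance, population substructure among founders, and
correlated multi-parameter plasma physiology (parameters are drawn
independently per member).

## Numerical and engineering choices

- All randomness flows from a single `numpy` `default_rng(seed)`;
  identical configurations produce byte-identical output files.
- VCF I/O: reading via cyvcf2 with multi-allelic records decomposed into
  one record per alternate allele (per-sample dosage recoded per allele; a
  genotype with any missing allele becomes a missing call); writing is a
  plain-text VCF v4.2 emitter with annotations in INFO keys
  (FUNC/SIFT/POLYPHEN/CADD/AF_<panel>), floats quantised to 6 significant
  digits, so write→read→write is a fixed point.
- Coordinates are 1-based VCF positions throughout; no interval type
  exists in the package.
- The pipeline report validates against `report.schema.json` using a small
  built-in structural validator covering the schema subset used
  (required/type/properties/items).
- Tests and the acceptance script size their simulations to the checks
  they make: 50 seeds at the default 20,000-variant configuration for
  recovery rates, 200,000 gene drops for the kinship Monte-Carlo oracle
  (3-standard-error agreement), 1,000-variant fixtures for brute-force
  cascade equivalence.

## Known limitations

- The subject-selection objective (summed kinship) is one reasonable
  formalisation; other objectives (e.g. minimising the maximum pairwise
  kinship) can select different subsets in pedigrees with ties.
- The exact test enumerates combinations in pure Python; the 10⁶-assignment
  ceiling keeps worst-case runtime near a second or two.
- Hemizygous male X genotypes are not modelled; sex chromosomes are
  treated as diploid.
- The cascade consumes annotations; it never computes consequence classes
  or prediction scores from sequence.
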