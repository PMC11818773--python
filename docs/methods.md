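# Methods

## Consequence classification

Variants are described at two levels — coding DNA (`c.`) and predicted
protein (`p.`) — and the two descriptions jointly determine a single
consequence class. Clinical tables do not state a classification
algorithm, so the package fixes one explicitly: a precedence ladder,
applied top-down, first match wins.

1. exon-level deletion/duplication (MLPA events, `del ex 57,58`) → **gross_del_dup**
2. any nonzero intronic offset in the cDNA description (`c.8245-2A>G`,
   `c.8244+3_8244+6del`) → **splice**
3. protein frameshift (`fsTerN`) → **frameshift**
4. small cDNA delins with a non-frameshift protein → **frameshift**
   (grouped with the small-indel class)
5. protein stop gain (`Ter`) → **nonsense**
6. single amino-acid substitution → **missense**
7. anything else → **inframe_other**

The ladder is deterministic and total. Two edge cases deserve note:
in-frame indels that create an immediate stop codon (an insertion whose
new codons include `Ter`, or a delins replacing one residue with several
ending in `Ter`) sit genuinely between the nonsense and frameshift
groups. Under this ladder a delins lands in the frameshift (small-indel)
group and a plain stop-gain insertion in the nonsense group; both carry
an `ambiguous_class` flag so reports can surface the convention.

Type distributions are computed over **distinct variants**, not alleles
(a variant seen on 27 chromosomes counts once); the allele-weighted
distribution is available as a secondary output. Report renderers round
percentages half-up to 1 decimal (2 in table output); recomputed values
are reported as computed, even where a published figure was rounded
differently (e.g. 16/75 = 21.3%, sometimes printed as 21.4%).

## Gene model

The transcript model is a user-supplied table of contiguous exon
intervals in cDNA coordinates. Positions with offset 0 map to the
containing exon; a positive offset is only meaningful at an exon end
(donor side) and maps to the following intron; a negative offset only at
an exon start (acceptor side), mapping to the preceding intron; other
anchor/offset combinations raise an inconsistency error. Range events
report every region they touch. No published exon coordinates ship with
the package, so model-derived labels are *cross-checked* against a
table's own region labels and mismatches are reported, never fatal —
published label columns are known to contain occasional inconsistencies
(e.g. an acceptor-site variant labelled with the downstream exon's
intron, or `c.5727-2A>G` labelled "Intron 38" beside exon-39 rows).

## ACMG evidence combination

The 2015 ACMG/AMP combining rules are encoded as minimal count
requirements over the four pathogenic strength levels (very strong /
strong / moderate / supporting), e.g. Pathogenic via
1 VS + {≥1 S | ≥2 M | 1 M + 1 P | ≥2 P}, Likely pathogenic via
1 VS + 1 M, etc. Each clause uses ≥ thresholds and the highest class
wins, which makes the verdict monotone: adding evidence never downgrades
it. Benign-side codes are accepted syntactically but excluded from
combining (conflict resolution is out of scope); strength modulation
(`PVS1_Moderate`) works through explicit overrides and is off by
default. A brute-force clause enumerator, kept independent in the test
suite, agrees with the engine on all 256 subsets of 8 representative
codes.

## Founder-based prevalence

The estimator assumes: (i) random mating (Hardy–Weinberg) for the
pathogenic allele pool; (ii) the cohort's founder share `f = a/A` is an
unbiased estimate of the founder's share of pathogenic chromosomes in
the population; (iii) the population database frequency `q` of the
founder allele is measured without ascertainment bias. Then
`Q = q/f`, `prevalence = Q²`, `carrier = 2Q(1−Q)`. The identity
`prevalence · f² = q²` holds exactly and is property-tested.

Inputs with `q/f > 1` are rejected as inconsistent. Display rounding:
"1 in N" at 3 significant figures, "per million" at 2; full-precision
values are always carried alongside.

Uncertainty uses a parametric bootstrap: `a* ~ Binomial(A, a/A)` and
`alt* ~ Binomial(total, alt/total)`, recomputing the prevalence per
replicate and taking percentile quantiles; replicates with `a* = 0`
(undefined founder share) are rejected, redrawn and counted. The
interval reflects only the two binomial sampling errors — not model
error from consanguinity, population structure or incomplete case
ascertainment, which the point estimate inherits silently. These are
documented limitations, not corrections the package attempts.

## Fisher exact test

Two-sided p-values follow the minimum-likelihood convention (the sum of
hypergeometric probabilities of all same-margin tables no more probable
than the observed one), the behaviour of mainstream statistics packages.
Grand totals ≤ 200 use exact integer arithmetic on unnormalised
hypergeometric weights, so probability ties are exact; larger tables use
log-gamma arithmetic with a relative tie tolerance of 1e-7 and a
log-sum-exp accumulation. A zero margin admits a single table and p = 1.
The odds ratio is the cross-product ratio, infinite when `b·c = 0` with
`a·d > 0`. The implementation is verified against a full-enumeration
rational-arithmetic oracle on every 2×2 table with row margins ≤ 30, and
against an established routine on a population-scale table.

## Synthetic cohorts

The generator emulates the structure the estimator assumes, which makes
the recovery tests well-posed rather than realistic:

- a pool of `n_pool_variants` distinct variants on a toy transcript
  (65 exons × 140 bp by default, matching the gene's exon count and
  approximate 9.1 kb coding length), classes drawn from `class_mixture`
  (default 0.400/0.293/0.214/0.053/0.040 for nonsense/frameshift/splice/
  gross-del/missense — the observed spectrum of the cohort the pipeline
  was built around);
- one designated founder allele (a single-base frameshift deletion);
  each patient chromosome is the founder with probability `f` (default
  0.15) and otherwise uniform over the non-founder pool, so the founder's
  marginal share is exactly `f`;
- patients are homozygous-by-descent with probability
  `consanguinity_rate` (default 0.05 — a few homozygotes per 90
  patients, as seen in real founder cohorts); chromosomes are otherwise
  independent (no assortative mating);
- the population sample sees the founder at frequency `true_Q · f`
  (defaults `true_Q = 0.0029`, 241,524 chromosomes).

What the generator does **not** emulate: linkage/haplotype structure,
ethnic substructure (a founder allele concentrated in one subpopulation),
ascertainment of severe cases, de-novo variation, or frequency error in
the reference database. Passing recovery tests therefore demonstrate
estimator correctness under its own assumptions, not robustness to their
violation.

All randomness passes through `numpy.random.default_rng` seeded per
stream from the config seed; every artefact is bit-reproducible.

## Problem sizes and numerical choices

Parameter-recovery tests run 200 replicates at the cohort's own scale
(90 patients, population sample 241,524) with 1,000 bootstrap replicates
each; the median estimated prevalence falls within 10% of the true `Q²`
and empirical 95%-interval coverage is ≥ 90%. The exhaustive Fisher
sweep covers all row-margin-≤ 30 tables. The packaged fixture (75
variants) drives every spectrum-level check. Unit tolerances: 1e-9
relative for Fisher-vs-oracle agreement on the exact path, 1e-6 against
the external routine on the log path; tie tolerance as above.

## Known limitations

- The consequence ladder trusts the protein annotation for frameshifts;
  it does not recompute reading frames from a reference sequence
  (reference-free by design, like the tables it consumes).
- Prevalence estimation uses a single founder variant; multi-founder
  joint estimation and birth-incidence vs point-prevalence adjustment
  are out of scope.
- The Fisher module handles 2×2 tables only; no mid-p correction, no
  multiple-testing adjustment.
- Genomic (`g.`) coordinates, VCF ingestion and 3'-normalisation against
  a transcript sequence are out of scope.
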