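# Methods

`phenoprio` automates candidate-variant prioritization for monogenic
sensorineural hearing loss (SNHL) from a single proband's exome: allele-
frequency filtration, ACMG-AMP 2015 classification with Bayesian posterior
tiering, and phenotype-to-disease semantic similarity ranking. This note
records the model, its assumptions, the tunable parameters, what the
synthetic benchmark does and does not show, and the design choices made
where the design was genuinely open.

## Pipeline model

A case is a single-sample VCF, a precomputed per-variant annotation sidecar
(gene, consequence, subpopulation allele frequencies, in-silico scores,
curated evidence flags), and the patient phenotype as a set of HPO terms.
The pipeline assumes a monogenic, Mendelian etiology — the setting in which
SNHL mostly sits — and ranks candidate (variant, disease) pairs rather than
bare variants, since one gene may carry several disease associations with
different inheritance modes.

### Step 1 — frequency filtration

A variant is removed when its allele frequency exceeds the BA1 bound
(default 0.05, strict `>`) in **any** subpopulation outside the founder set
(default {Finnish, Jewish}; founder bottlenecks inflate frequencies of real
pathogenic alleles). Curated exceptions — variants asserted pathogenic
despite being common, such as the mild GJB2 alleles p.Met34Thr and
p.Val37Ile — are exempted via a `filter_exempt` flag in the known-variant
table. An absent frequency is treated as *rare, not zero-evidence*: a novel
variant must survive filtration, and absence is itself evidence for PM2
later. The optional `hearing_loss` profile adds the stricter
disease-specific total-MAF bounds used in expert manual curation: recessive
candidates are dropped when total MAF > 0.005 (strict), dominant ones when
total MAF ≥ 0.001 (boundary excluded, following the published inequalities
exactly); X-linked and mitochondrial candidates use the dominant bound, the
stricter of the two, since no separate bound is published for them. When
databases disagree, the maximum across provided subpopulations governs.

### Step 2 — ACMG-AMP classification and Bayesian tiers

Criteria are assigned by a deterministic rule table over the sidecar's
curated flags (see `acmg.assign_criteria`); notable conventions:

* **PM2** requires every provided frequency below `pm2_threshold`
  (default 1e-4) or no observation at all. "Absent from controls" is
  unquantified in common usage; 1e-4 is well below any plausible carrier
  frequency for a dominant allele.
* **PP3/BP4** need ≥ 2 concordant in-silico scores (REVEL, ada_score,
  rf_score; each calibrated so > 0.5 predicts damage); a single score
  suffices when only one tool reported, since one tool then *is* the
  consensus.
* **PM3** applies to a homozygote, or to a heterozygote whose gene carries a
  second retained variant with a pathogenic/likely-pathogenic assertion.
  Without phase data the trans configuration is assumed and the output
  carries a `pm3_assumed_trans` flag.
* Criterion strengths are never modulated (no PVS1 downgrade tree, no
  disease-specific strength adjustment); every criterion scores at its
  code-prefix default. The hearing-loss expert specification of the
  guidelines is deliberately not implemented, keeping the engine comparable
  across Mendelian disorders.

The categorical class comes from the 2015 combining table, implemented over
evidence-strength counts and verified in the test suite against an
independent enumeration of every criteria multiset of size ≤ 6. Conflicting
pathogenic and benign evidence, like insufficient evidence, yields VUS.

The posterior probability of pathogenicity uses the point-based Bayesian
reading of the guidelines: supporting/moderate/strong/very-strong evidence
is worth 1/2/4/8 points (benign evidence −1/−4; stand-alone BA1 is scored
−8, though classification handles it categorically first), and

    odds = odds_vs ** (points / 8),   posterior = odds·prior / ((odds−1)·prior + 1)

with prior 0.1 and odds_vs 350. On that scale the tier cutoffs are strict
posteriors: tier 1 > 0.9, tier 2 > 0.499, tier 3 > 0.1; a posterior ≤ 0.1
(at or below the prior) gets no tier and is never selectable. The empty
criteria set returns exactly the prior, and the posterior is monotone in
added evidence — both property-tested.

### Step 3 — phenotype similarity

Term information content is estimated from the knowledge base's own
disease–HPO annotations: annotations propagate to ancestors and
IC(t) = −ln(n_t / N) over N diseases. Terms never annotated receive the
maximum observed IC, so an unusual patient term neither dominates nor
vanishes. Pairwise similarity is Resnik's measure (IC of the most
informative common ancestor); profiles are compared by a symmetric
best-match average (BMA), normalized by the patient profile's
self-similarity and capped at 1. The denominator is role-specific by
design: ranking only needs cross-disease comparability for one fixed
patient, and self-normalization puts a perfect phenotype match at 1. The
symmetric core (`symmetric_bma`) is exactly exchange-symmetric and is
tested as such. One subtlety: adding a *weakly* informative patient term to
a disease profile can dilute the disease-to-patient mean and lower the
normalized score; only adding the patient's most informative term is
guaranteed non-decreasing, and that is the property the suite asserts. A
Jaccard-over-ancestor-sets metric is available (`similarity_metric:
jaccard_ancestors`) for checking rank robustness; absolute scores are not
comparable across metrics, only rankings.

An empty patient term set is accepted (phenotype-free mode): similarity is
0 with a warning, so classification and tiering still rank candidates.

### Selection

Candidates are ranked by (tier ascending, similarity descending, posterior
descending, genomic coordinate ascending) — the tier dominates, phenotype
fit orders within a tier, and the last two keys are a deterministic
tie-break convention. Genotype–inheritance consistency is enforced before
ranking: a recessive diagnosis needs a homozygote or ≥ 2 distinct retained
heterozygotes in the gene; a single heterozygote in a recessive-disease
gene (monoallelic AR) is kept in the output for audit but is unrankable.
This is deliberate: promoting a monoallelic recessive allele on phenotype
specificity alone requires predefined genotype–phenotype priors that only
expert curators apply, and `allow_monoallelic_ar=True` exists precisely to
reproduce that human override. The top-ranked variant is selected, plus its
trans partner when the top disease is recessive and the genotype compound-
heterozygous; an empty ranked list yields status `not_found`. Benign and
likely-benign classifications are never candidates. Identical inputs and
configuration produce byte-identical result JSON.

## Synthetic spike-in benchmark

The benchmark emulates an in-silico validation panel: 21 synthetic exome
VCFs, each of 60,000–90,000 common background records (drawn uniformly per
case) plus one implanted known deafness variant (or a biallelic pair for
recessive genes) with inheritance-appropriate zygosity, and the patient
phenotype set from the matched disease profile. Background sites are
simulated on exome-like coordinates with every subpopulation AF drawn from
(0.10, 0.5], so by construction every background record fails BA1 and the
candidate set per case is exactly the spike — which is what makes recall@1
a filtration-plus-classification test rather than a ranking stress test.
The background is generated, not sampled from real population VCFs, so the
benchmark runs offline and deterministically per seed; consequences of that
choice: no linkage structure, no indel-rich regions, no genotyping error,
and background AFs that are uniform rather than SFS-shaped. Passing recall
therefore demonstrates the pipeline's plumbing and rule correctness under
the stated frequency conditions, not performance on real exomes.

The 21 packaged spike plans span 9 dominant singles, recessive homozygotes
and compound heterozygotes (including the common, filter-exempt GJB2 pair —
the case class where naive BA1 filtering silently drops the causal
variant), one X-linked hemizygote, and one mitochondrial case. A reduced
5,000-record background mode runs the whole benchmark in seconds and is
what the continuous test suite uses; `scripts/acceptance.py` runs the full
scale (about two and a half minutes on one CPU).

## Concordance comparator

Two per-case result sets are compared by exact set equality of selected
variants under normalized (chrom, pos, ref, alt) identity — HGVS strings
are display-only, so nomenclature dialects cannot split a match, and
partial overlap counts as discordant. The case-level concordant call rate
is 100 × concordant/total, rounded half-up to 2 decimals; per-ACMG-class
rates count variants, with the union of both analysts' calls in a class as
denominator. Zygosity is not part of match identity.

## Degenerate inputs and numerical notes

* Multi-allelic VCF records are split per carried ALT; uncarried ALTs are
  not emitted. Haploid genotypes on X/Y/MT read as hemizygous.
* Allele normalization trims shared suffix then prefix (left-alignment to
  the minimal representation), keeping at least one base each.
* A VCF/KB genome-build mismatch aborts the case; fixtures declare GRCh37.
* Duplicate annotation keys, frequencies outside [0, 1], and ontology
  cycles are hard errors; obsolete ontology terms are dropped on load.
* The demo knowledge base is a hand-built synthetic stand-in (23 disease
  profiles, 28 curated variants, a 40-term mini-ontology); real deployments
  load their own KB directory with the same schema.

## Known limitations

* Copy-number variation is out of scope: deletion-driven diagnoses (e.g.
  STRC, POU3F4-upstream) cannot be reached from a point-variant VCF.
* No segregation analysis across family members, no phasing: PM3 is an
  assumption, flagged as such.
* Curated evidence flags are inputs; the engine does not mine literature.
* Absolute similarity scores depend on the KB's annotation corpus; only
  within-case rankings are meaningful.
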