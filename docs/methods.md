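# Methods

## Scope and model

`panelburden` implements the analysis chain of diagnostic multi-gene panel
testing for hereditary breast cancer in BRCA1/2-negative index patients:
rule-based five-tier variant classification on eight predisposition genes
(ATM, CDH1, CHEK2, NBN, PALB2, RAD51C, RAD51D, TP53), followed by
gene-level carrier-burden case-control statistics against external control
cohorts and case-case comparisons across clinical strata. Because the
underlying patient-level data of such studies are not public, the package
ships two data sources of its own: a synthetic cohort generator
(`panelburden.simulate`) and a deterministic pseudo-cohort reconstructed
from published carrier-count margins (`panelburden.reference`).

## Variant classification rules

Classes follow the IARC five-tier scale (1 benign … 5 pathogenic; classes
4/5 are pooled as "deleterious" downstream). The rules, in precedence
order as applied by `assign_class`:

1. **Per-variant override.** An explicit entry (gene + variant key) forces a
   class. This is the only route to class 4 in this implementation — the
   pooled "class 4/5" reporting convention leaves no separate operational
   criterion for "likely pathogenic", and we prefer not to invent one. The
   canonical use is demoting a population-specific low-risk allele (the
   CHEK2 p.I157T pattern) or promoting an established pathogenic missense.
2. **Frequency.** A variant with minor allele frequency ≥ 1% in *any*
   configured reference population is benign (class 1). The maximum across
   populations is used; an unobserved frequency counts as rare, since
   panels routinely find novel variants.
3. **Protein-truncating variants** (nonsense, frameshift, essential splice —
   the invariant ±1/±2 intronic dinucleotides or the last nucleotide of a
   donor exon) are class 5, *unless* the truncation falls in the
   **NMD-escape zone**: the last coding exon plus the final 55 coding
   nucleotides of the penultimate coding exon. In-zone truncations are VUS
   (class 3) unless the truncated tail `[anchor, CDS end]` intersects a
   supplied protein-domain interval, which restores class 5.
4. Everything else is a VUS (class 3).

Independent of the class, rare missense variants (all MAFs < 0.1%) called
"damaging" by **both** of two configured in-silico predictors are flagged
`damaging_missense` for the missense burden analysis. Predictor names are
configuration, not code.

Choices where the rule text is underdetermined:

* **NMD anchor.** For nonsense and missense SNVs the anchor is the first
  altered codon's start; for frameshifts it is the first altered coding
  base. Computing the downstream novel stop would require the full coding
  sequence at classification time and changes nothing for the zone test in
  the common case; the anchor-based rule is the conservative default.
* **"Domain disrupted"** is read as *intersection* of the truncated tail
  with any domain interval (truncation removes everything downstream); a
  stricter "domain fully lost" mode is available via `domain_mode`.
* **Coding-base counting.** The 55-nt window is counted in coding
  nucleotides of the penultimate *CDS-bearing* exon; purely non-coding
  exons are ignored, since NMD escape is a property of where the premature
  stop sits relative to the last exon-exon junction of the CDS.
* **Single-coding-exon transcripts** have no downstream junction, so the
  whole CDS is escape territory; such calls carry a `single_coding_exon`
  audit note.
* **Final-intron splice variants** are evaluated against the zone via the
  first coding base of the last coding exon and flagged
  `final_intron_zone_eval`; splice variants of upstream junctions truncate
  before the last junction and are never demoted by the zone rule.

Coordinates are 1-based closed throughout (VCF/GFF3 convention); CDS
positions count from the A of the initiator ATG, introns use HGVS-style
±offsets. Transcript models load from GFF3 (gene→mRNA→exon/CDS) or from a
YAML document with fields `gene, transcript_id, chrom, strand, exons
[[start,end],…], cds [first,last coding base], domains [{name, aa_start,
aa_end},…]`; domains may also come from a sidecar TSV
(`transcript_id, domain_name, aa_start, aa_end`, protein coordinates).

## Burden statistics

Carriers are counted per patient: a patient with several qualifying
variants in a gene — or, for the all-gene row, in several genes — counts
once. For a 2×2 carrier table with `a` carriers of `a_n` cases and `b`
carriers of `b_n` controls,

    OR = [a/(a_n−a)] / [b/(b_n−b)]
    95% CI = exp( ln OR ± z₀.₉₇₅ · √(1/a + 1/(a_n−a) + 1/b + 1/(b_n−b)) )

with z₀.₉₇₅ = 1.959963984540054. This Wald form is identical to the
exponentiated slope of a univariate logistic regression on the same table
(the equivalence is asserted against a statsmodels GLM fit in the test
suite), which is why a closed form reproduces ORs reported from logistic
fits. Any zero cell renders the estimate undefined, reported as "n.a."
with **no** continuity correction — matching the reporting convention of
the tables this package regresses against. Significance uses the
two-sided Fisher exact test (point-probability method, delegated to
scipy.stats.fisher_exact and cross-checked against full hypergeometric
enumeration); degenerate margins return p = 1 with a warning. Age-at-
diagnosis comparisons use the pooled-variance Student t-test (Welch behind
a flag); `vs_rest` mode removes the carriers' ages from the reference
multiset, `vs_overall` compares against the full sample. No multiplicity
adjustment gates significance (the source analyses used raw p < 0.05); a
Benjamini–Hochberg column is emitted in rendered tables as supplementary
output only. Rendered tables round half-away-from-zero to 2 decimals; the
JSON twins keep machine precision.

Strata with unknown attributes (receptor status unavailable) are excluded
from both denominators of that stratum, mirroring the "status available"
subgroup convention.

## Synthetic cohort generator

`simulate_cohort` emulates the study conditions: 5589 cases, control
cohorts of 27,173 / 7325 / 2189, and per-gene carrier probabilities set to
the published prevalences (e.g. deleterious-PTV carrier probability
71/5589 for ATM against 96/27,173 in the ExAC-like cohort). Structure:

* **Phenotypes** are drawn from the published margins: bilateral 11.25%,
  OC family history 16.7%, receptor status available 55.5% with ER+ 75.9%,
  PR+ 70.5%, HER2+ 21.2% as independent margins (no joint receptor
  distribution is published). Age at first diagnosis is a truncated normal
  with mean 46.7, SD 11, range [17, 92]; the SD is not published and was
  chosen once so the printed age-band fractions (≈26% < 40, ≈38% 40–49)
  are approximately reproduced. 49/5589 ages are set missing.
* **Carrier status** per gene is Bernoulli with phenotype-dependent odds:
  log-odds offsets for bilateral disease, ER-negative and HER2-positive
  status at the case-case odds ratios reported per gene (PALB2 bilateral
  2.07, TP53 3.30, CHEK2 HER2+ 2.33, …), with the intercept calibrated by
  bisection so the marginal prevalence equals the configured probability
  exactly. Carriers' ages are shifted by the per-gene difference of the
  published carrier means (TP53 −7.0 years, …) before re-clipping.
* **Variants.** Each counted carrier receives a concrete allele on a
  fabricated transcript with realistic CDS length and exon count: a
  nonsense SNV upstream of the NMD-escape zone, a 1-bp frameshift
  deletion, an essential-splice SNV of a non-final intron, or (for a
  configured fraction) an in-zone nonsense rescued by a domain — all of
  which classify as class 5 through the real engine. CHEK2 carriers share
  a recurrent founder frameshift (c.1100del-like) at the published 79/103
  fraction. Additional layers exercise the non-deleterious paths:
  unrescued in-zone truncations (VUS), missense VUS, rare
  damaging-missense variants at the published CHEK2/TP53 prevalences
  (other genes get modest near-null defaults, as only prevalence
  directions are published for them), and one common MAF ≥ 1% variant per
  gene (class 1). Pathogenic missense carriers are expressed through the
  generated override list; their predictor verdicts are deliberately
  non-consensus so the damaging-missense layer stays at its configured
  rate.
* **Controls** are per-individual Bernoulli matrices per cohort, so
  per-gene counts, the deduplicated all-gene count and the founder subset
  are mutually coherent; damaging-missense control counts are binomial.
* **Determinism.** All randomness derives from the single config seed
  through named child generators; re-running produces byte-identical
  VCF/GFF3/FASTA/TSV output. `dual_carrier_count`, when set, moves
  carrierships between patients deterministically until exactly that many
  patients carry two variants, preserving every per-gene marginal; unset,
  genes are independent (expected dual count ≈ 4 at default prevalences,
  the same order as the observed 2).

What the generator does **not** emulate: joint receptor-status
correlation, recurrence structure of non-founder variants (each simulated
VUS is unique, so distinct-variant counts exceed the published ones),
linkage/haplotypes, sequencing error, and variant-level control
frequencies. Tests passing on simulated data therefore certify the
pipeline's arithmetic and rule logic under the published margins, not the
biological realism of any particular variant spectrum.

## Pseudo-cohort from published counts

`reference.fixture_cohort` reconstitutes 5589 individual patients whose
per-gene, per-stratum carrier counts equal the printed tables *exactly*:
the 339 class-4/5 carriers (341 variants, two dual carriers — ATM+CHEK2
and NBN+RAD51C, both unilateral and outside the receptor subgroup), the
272/274 PTV carrier split, the CHEK2 founder subset with its own bilateral
and receptor margins, the NBN-bilateral zero, and the ER/PR/HER2/TNBC
margins of the 3104-patient receptor subgroup. Joint receptor triples are
assigned by a wrapped-block construction that honours all four margins per
carrier group without creating unintended triple-negatives; construction-
time assertions re-verify every margin on each call. Ages reproduce each
gene's published carrier count/mean/range (deterministic integer lists);
within-group spread is synthetic, so t-test p-values on this fixture are
illustrative rather than reproductions. Three published cells are known to
be inconsistent with their own printed counts (CHEK2 2.93 and founder 3.02
vs the ExAC-like cohort, all-carrier bilateral 1.50); the pipeline reports
the cross-product of the counts (2.95, 3.05, 1.47) and a regression test
documents the deviation.

## Problem sizes used in the automated checks

Simulation-based checks run at the study scale of 5589 cases against the
27,173-strong control cohort: estimator recovery uses 200 replicate
carrier draws for the three common genes (ATM, CHEK2, PALB2 — genes whose
expected counts keep the log-OR estimator defined in essentially every
replicate; conditioning rarer genes on definedness would itself bias the
check), and Wald CI coverage uses 1000 replicate 2×2 draws at true OR 3.6.
Oracle equivalence checks use 100 random small tables (Fisher vs
enumeration), 50 tables (OR vs logistic fit), and 500 PTV anchors per
transcript geometry (engine vs literal rule text).

## Known limitations

* Class 4 is reachable only via the override list (see above).
* HGVS p. parsing is minimal (the `Ter`/`fs`/`=`/missense patterns needed
  for annotation fallback), not a general HGVS implementation.
* Large genomic rearrangements / CNVs are out of scope, as is running the
  in-silico predictors themselves — verdicts are consumed as annotations.
* Multi-exon-spanning complex alleles beyond anchored indels and
  equal-length substitutions are classified `other`.
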