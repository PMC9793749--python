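# Methods

## Problem and model

`ctvar` post-processes annotated RNA-seq variant calls from a multi-specimen
liver-cancer cohort to isolate variants that behave like circulating tumor
markers: present in the tumor and detectable in the same group's plasma (or
EVs), and never observed in any control compartment. The package deliberately
starts *after* variant calling — its inputs are SnpEff-annotated VCFs plus a
cohort sheet — because alignment and calling are upstream concerns with
mature tooling, while the group-level concordance logic is what needs to be
explicit, audited and testable.

### Variant identity

A variant is identified by (chrom, pos, ref, alt), 1-based VCF coordinates.
Multi-allelic records are split into one key per alternate allele, and keys
are parsimony-trimmed (shared suffix removed first, then shared prefix with
position adjustment, always retaining one base per allele). This
normalization needs no reference genome and is sufficient for cross-sample
identity of the indel representations the upstream callers emit; full
left-alignment against a FASTA is out of scope.

### True-positive calls

A call is a true positive iff depth ≥ `depth_min` (default 5) **and** QUAL ≥
`qual_min` (default 20), both bounds inclusive. QUAL is interpreted as
−log₁₀(p) of the call; whether an upstream caller emitted a likelihood-based
QUAL or an exact-test −log₁₀(p), the filter treats it as the same scalar and
the run metadata records the convention. Depth is taken from INFO/DP when
present, else from summed FORMAT/AD, tolerating caller dialects. Genotype and
allele-fraction fields are ignored: presence is call-based, and exclusion is
evaluated on passing calls only — a control sample carrying only a
sub-threshold call does **not** veto a candidate, so the true-positive
definition governs presence and absence symmetrically.

### High-risk restriction and impact

A variant's impact is the maximum across its transcript annotations
(HIGH > MODERATE > LOW > MODIFIER), because the analysis filters variants,
not transcripts. The presence matrix retains variants whose maximal impact is
in `impact_keep` (default {HIGH}); the normal-liver veto consequently acts on
HIGH-impact presence, the same matrix as everything else.

Effect terms map onto seven region bins (splicing > exon > intron > upstream
> downstream > intergenic > genic_other, first match wins) and four
functional classes (nonsense ≻ missense ≻ synonymous ≻ none); both mappings
are fixed here because upstream annotation lists the bins without defining
them.

### Once-only counting and the cascade

Group-level presence is per (group, specimen) stratum: membership is "≥ 1
passing sample carries it", and the within-stratum sample frequency is kept
as a descriptive column. There is no minimum-frequency gate by default; a
stricter reading ("only the most frequent variants") is exposed as
`min_frequency` (default 0). The tumor-centric cascade requires HCC-tumor
and HCC-plasma membership and vetoes on LC-plasma, NHC-plasma and
normal-liver membership; every veto is recorded per candidate. CCA specimens
participate in neither side of the HCC derivation — the CCA set is derived
by the identical cascade with CCA in the case role and compared to the HCC
sets by a containment fraction (undefined/NA for an empty query set).
All emitted sets are sorted by (natural chromosome order, pos, ref, alt).

The per-subject analysis decomposes each cancer subject's plasma/tumor/EV
presence sets into exact Venn regions; the pooled triple-concordant set is
the union of three-specimen centers minus anything seen in any control
sample. Subjects with fewer than two specimens are skipped.

### Selection statistics

Per candidate, the 2×2 table counts case plasma samples with/without the
variant against pooled control plasma. The test is one-sided
(case-enriched): the biological question is exclusive presence in cases, and
the sidedness is configurable and logged. The BH family is exactly the
candidate list passed in, not the whole matrix, and selection uses q ≤ 0.05
by default. Over-representation is an upper-tail hypergeometric test per
gene set, intersected with a universe that defaults to all genes carrying
any matrix variant. Fisher and hypergeometric tails come from scipy and BH
from statsmodels; the test suite cross-checks both against exhaustive
same-margin enumeration and a naive O(m²) step-up implementation.

A note on BH: the step-up transform is *not* idempotent in general
(p = [1.0, 0.25] adjusts to [1.0, 0.5], which re-adjusts to [1.0, 1.0]), so
the package asserts the properties that do hold — q ∈ [0,1], q ≥ p,
monotonicity in p-rank, permutation equivariance.

### Heat-map ordering

Sample ordering for occurrence heat-maps is hierarchical clustering on
binary profiles with Jaccard distance and average linkage (the metric and
linkage are configurable; this default is recorded in output metadata).
Columns are canonically pre-sorted by sample id before clustering so leaf
order is deterministic and invariant to input column permutation; pairs of
all-empty profiles get distance 0.

## The synthetic cohort generator

The generator's default design *is* the study condition set: 46 samples
(14 HCC plasma, 6 matched tumors, 5 matched EVs with 4 subjects carrying all
three specimens and 3 carrying two, 8 LC plasma, 6 NHC plasma, 1 normal
liver, 2 CCA subjects with three specimens each); 200 background variants,
30 control-shared traps, 50 tumor-centric targets, 12 EV-enriched variants;
tumor carrier frequency uniform on [0.30, 1.00] and plasma on [0.07, 0.50]
(carrier counts k = max(1, round(f·n)), which keeps realized frequencies
inside the ranges); impact marginals MODIFIER/HIGH/LOW/MODERATE =
0.943/0.023/0.023/0.011 (a transcriptome-wide 94.3/2.3/2.3/1.0 pattern, with the
leftover mass assigned to MODERATE so the marginals sum to one); HIGH-impact
effects weighted toward splice donor/acceptor and frameshift, with
frameshift variants realized as indels. Positions are drawn without
replacement from a synthetic two-chromosome space — no reference FASTA is
needed because ingestion does not re-align. Gene symbols come from a generic
pool (`GENE0001`…), so panel-based summaries are exercised with hand-built
fixtures rather than generator output.

Noise has two dials: a per-stratum dropout δ (a carrier's call is simply not
emitted) and a sub-threshold-QUAL fraction (a call is written with
QUAL < 20). Both default to 0, making the default cohort exactly
recoverable; depth is drawn as floor + negative binomial (mean 30,
dispersion 5) and therefore never fails the depth filter by construction —
sub-threshold mass is carried by QUAL alone. The closed-form expected recall
of a planted tumor-centric variant with carrier counts (k_t, k_p) is
(1 − e_t^{k_t})(1 − e_p^{k_p}) with per-call miss probability
e = 1 − (1 − δ)(1 − f_sub); the design-level expectation integrates over the
carrier-count distribution induced by the uniform frequency draw. The
3σ band used in the stochastic tests comes from the exact Bernoulli variance
Σ pᵢ(1 − pᵢ) of the per-variant survival indicators.

Determinism: one seed feeds a cohort-level stream (variant identities,
classes, carriers) and per-sample streams derived by stable SHA-256 hashing
of the sample id (depth, QUAL, dropout), so identical seed + design gives
byte-identical VCFs and adding a sample leaves other samples' noise
untouched. The generator asserts that no tumor-centric or EV-enriched
variant is ever written into an LC/NHC sample, and background variants are
forced into ≥ 1 sample of every group, so a high-impact background variant
can never masquerade as tumor-centric.

### What the generator does and does not emulate

It reproduces the cohort layout, matched-set structure, carrier-frequency
ranges, impact marginals and depth/QUAL filtering regime — enough to prove
the set algebra, the vetoes, the frequency accounting and the selection
statistics correct against planted truth. It does **not** emulate read-level
error, alignment artifacts, shared germline structure, linkage, expression-
dependent detectability, or realistic gene assignment. Passing tests
therefore certify the *logic* of the pipeline, not the biological discovery
rate on real cohorts; headline set sizes from real data (thousands of
variants) are outside desk-scale reach and are not reproduced.

## Problem sizes used by tests and the acceptance script

The default planted design (46 samples, 280 variants) runs the full
file-based pipeline in seconds. Stochastic recall is measured over 200
replicate cohorts in the test suite (in-memory generation) and 60 in the
acceptance script; impact marginals are checked over 12,000 simulated
variants against binomial 99% confidence bands. These sizes are the
package's chosen verification scale: large enough for the 3σ and CI
arguments to bind, small enough to run anywhere.

## Known limitations

- No reference-based left-alignment: pathological indel representations that
  need a FASTA to normalize will not match across callers.
- Once-only counting means a single passing control call vetoes a candidate;
  with noisy controls the cascade is conservative by design.
- The liver-specific panel ships with the six named transcripts (FGL1,
  CYP2E1, SERPINA1, ALB, TF, SYCE1) and is user-extensible; the full
  32-transcript panel is not published.
- The ORA is a plain hypergeometric over user-supplied GMT sets; no pathway
  database content is shipped.
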