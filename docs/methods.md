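# Methods

This note documents the models and procedures the package implements, the
defaults that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Reference Z-scoring

The universal expression unit is the reference Z-score
`Z_p = (x_p − μ_p) / σ_p`, with μ_p and σ_p the per-probe mean and *sample*
standard deviation (n − 1 denominator) across the normal-tissue reference
arrays. Two or more reference samples are required; the emulated study used
five.

- **Scale.** Z-scores are computed on the intensity scale as received
  (MAS5-style normalized intensities). `log2_transform=True` applies
  log2(x + 1) to intensities before both statistics and scoring, for users
  who prefer variance-stabilised units; the default is off.
- **Zero variance.** A probe with σ_p = 0 has no defined Z and is *dropped*,
  with the reason recorded in the profile's `dropped_features` audit map,
  rather than patched with a pseudo-variance. Every later mapping stage
  carries this audit map forward, so the union of valued and dropped
  features always partitions the input.
- **Small-reference caveat.** With n = 5 reference samples the null
  distribution of Z has Student-t-like tails (≈ t₄ scaled by √(1+1/n)), not
  normal ones: about 14 % of truly null genes fall outside |Z| < 2. The
  DEG threshold of 2.0 therefore admits a non-trivial null fraction; this
  is a property of the emulated study design, not of the implementation.

## Cross-species mapping

Probes average (arithmetic mean) into canine genes; canine genes translate
to human genes only when the homolog pair is unique in both directions
("ambiguous homology" otherwise — ambiguity is data to audit, never
resolved heuristically); human genes can be replicated onto human probe
sets for stores keyed by probe id. Scoring defaults to the human-gene
level: replicating first would let multi-probe genes cast several votes in
the rank-based methods. Translation never alters a Z value, and under a
fully 1:1:1 chain the Z multiset is conserved end to end (property-tested).

## The five prediction methods

All methods consume a human-gene Z-profile and the knowledge base; all
p-values live in (0, 1] and are floored at 1e−16 before any log transform.

**Biomarker rules.** A rule fires when its comparator holds strictly
(`Z > θ` or `Z < θ`). Per drug, firing indicate-rules produce one
indicated prediction scored by the largest qualifying |Z| with
p = Φ̄(score); firing contraindicate-rules produce a *separate*
contraindicated prediction. Rules on unmeasured genes are recorded as
non-evaluable in the evidence list. The per-rule weight field exists but is
fixed at 1.0 and never read — disease-context weighting is out of scope.

**Drug target expression.** A drug is indicated iff it *inhibits* at least
one target with Z ≥ +3 (inclusive); score = best target Z, p = Φ̄(score).

The one-sided normal-tail p-values of these two methods are this package's
own construction: they are monotone in evidence strength, bounded, and
compatible with the ensemble's −log10(p) sum. They are not calibrated
against any empirical null and should be read as ranking statistics.

**Drug response signatures (connectivity reversal).** DEG selection takes
genes with |Z| ≥ 2.0; if more than 500 qualify, the 500 of largest |Z| are
kept (ties broken by gene id ascending, for cross-platform determinism).
For a gene set at 1-based positions r(1) ≤ … ≤ r(t) in a rank profile of
length n,

    a = max_j [ j/t − r(j)/n ],   b = max_j [ r(j)/n − (j−1)/t ],
    ks = a if a > b else −b,

and the connectivity is (ks_up − ks_down)/2 when both sets are non-empty,
otherwise ks_up or −ks_down. Positive connectivity means the drug mimics
the disease signature; negative means it reverses it. Note the statistic is
bounded by, but does not attain, ±1 for finite set sizes (the extremal
placement gives (1 − t_up/n + (n − t_down + 1)/n)/2).

A drug's score is the arithmetic mean of connectivity over its signature
instances; only reversing drugs (score < 0) are candidates. The p-value is
one-sided toward reversal over `n_perm` random query sets of the same
up/down sizes drawn without replacement from the gene universe, with the
+1/(n_perm + 1) correction so p is never zero. The null permutes the query
set, not the reference rank lists — the simplest reproducible null — and
one shared set of draws is evaluated against every drug's instances. The
seed is an explicit parameter everywhere.

**Drug sensitivity signatures (PGSEA).** With profile mean μ and sd σ
(ddof = 1) over all measured genes, each set gene contributes
`v_g = μ + s_g (Z_g − μ)` where s_g = +1 for sensitivity-associated and −1
for resistance-associated genes; the statistic is
`zstat = (mean(v) − μ) √m / σ` over the m ≥ 2 measurable set genes, with
p = Φ̄(zstat) and only zstat > 0 predicted. Folding resistance genes *about
the profile mean* (rather than raw negation) makes the statistic exactly
invariant under adding a constant to every Z, and coincides with raw
negation whenever a set is sensitivity-only. Genes absent from the profile
are skipped; a drug whose measurable set falls below 2 genes is skipped
(not an error); a zero-variance profile is an error.

**Network target activity.** "Downstream" means direct transcriptional
out-edges only (path depth 1) — deeper propagation would make the exact
hypergeometric null intractable and the behavior hard to audit. For target
u with regulon D(u) and k DEGs among it, p is the hypergeometric upper
tail of ≥ k DEGs in |D(u)| draws from the gene universe. The activity sign
is (concordant − discordant), a DEG being concordant when
edge-effect × DEG-direction = +1; u is active iff p < α (default 0.05) and
sign > 0. A drug is predicted iff it inhibits an active target, scored by
−log10 of its best target p. Targets absent from the network are
non-evaluable, never failures.

## Ensemble

Indicating methods contribute −log10(p) (base 10, fixed for
comparability); the ranking key is (indicating-method count ↓, summated
score ↓, drug id ↑). The count-first key is a deliberate reconstruction of
"weighted by the number of methods which predict the drug": method
agreement is treated as stronger evidence than any single method's
p-value, and multiple-target frequency is already reflected inside method
scores via their evidence. Contraindicated drugs are excluded from the
main ranking and listed separately with their evidence — the conservative
reading of a DO-NOT-recommend rule, since no interaction rule with
positive evidence is defined.

## QC gate and turnaround

Stage order: shipping → RNA QC (primary lab) → pathology → RNA re-QC
(profiling lab) → cDNA → array; first failure wins; the first three stages
are mandatory, later stages are evaluated only when measured. Boundary
semantics are exactly as operated: yield strictly > 20 ng; A260/280 ≥ 1.8;
RIN ≥ 6.0; tumor ≥ 50 %; normal strictly < 50 %; necrosis ≤ 20 %;
background strictly < 100; percent present strictly > 30; scale factor
strictly < 100.

- **Two pathology reads** combine by arithmetic mean before thresholding.
  A per-read AND rule would fail two cohort samples that the study
  profiled (one with a 50 % normal first read, one with a 25 % necrosis
  second read); the mean rule reproduces every published verdict.
- **Missing RIN** (instrument software error) passes only under an explicit
  electropherogram visual-inspection override flag, mirroring the two
  cohort cases where that occurred. The re-QC lab applies the same
  thresholds.
- **Effective day 1** is the receipt date unless that is a Friday, weekend
  or holiday, in which case the next business day (samples are not shipped
  onward into a weekend). Turnaround is the inclusive business-day count
  from effective day 1 through the report date; a report released on a
  non-business day additionally counts the calendar days past the last
  business day (a Sunday report costs its weekend). This is the only
  convention consistent with all 13 published adjusted turnaround values,
  and it is deliberately *not* monotone across weekend report dates: a
  Sunday release counts worse than the following Monday would.
- The holiday calendar is configuration; the cohort fixture contains
  exactly {2011-09-05}.

## Synthetic data

The generator emulates: a 5-sample reference of log-normal intensities
(meanlog 6, sdlog 1 across probes; multiplicative noise sdlog 0.15 across
samples), 200 genes with 1–3 probes per gene on each platform, a strict
1:1:1 mapping chain, 20 up- and 20 down-planted genes shifted by 4
empirical reference sds (so the expected gene-level Z equals the effect),
and a 10-drug knowledge base in which one planted drug's evidence in every
store is concordant with the plant while decoys carry random evidence
drawn from the unplanted gene pool. Expressing effects in sd units keeps
recovery thresholds analytic; all draws are deterministic in the seed.

Not emulated: cross-hybridisation, batch effects, correlated co-expression
modules, realistic present-call structure, or real drug/target content.
Recovery tests therefore demonstrate the pipeline's arithmetic, plumbing
and determinism — not performance on real arrays.

Problem sizes used by the test suite and the acceptance script (package
defaults, chosen to keep the permutation floor meaningful at small cost):
50 recovery simulations at the default conditions with 300 permutations
per run, a 10-run no-plant null control, and 10,000 permutations for the
enumeration-vs-Monte-Carlo oracle checks on universes of ≤ 8 genes.

## Known limitations

- The biomarker-rule and target-expression p-values are ranking
  constructions, not calibrated tail probabilities.
- The permutation null conditions on DEG set sizes only; it does not
  preserve inter-gene correlation (none exists in the generator).
- Network inference is depth-1; regulatory cascades are invisible.
- The QC gate evaluates recorded measurements; it cannot represent
  partially-measured stages (a stage is present or absent as a whole).
- Knowledge-base stores are miniature stand-ins; nothing here reconstructs
  real drug-target, sensitivity-signature or interaction-network content.
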