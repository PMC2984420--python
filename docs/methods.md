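# Methods

## The analysis

`mirstab` asks whether the sequence conservation of microRNA precursors
(pre-miRNAs) is correlated with the thermodynamic stability of their hairpin
secondary structures. The pipeline takes per-record (sequence, dot-bracket
structure, folding free energy) triples — typically RNAfold output — together
with a per-nucleotide conservation track and a miRNA family table, and runs
four stages:

1. **Features.** Stability is measured by the adjusted minimum free energy,
   AMFE = −MFE / L × 100 (kcal/mol per 100 nt, L the sequence length), which
   removes the linear dependence of MFE on length; larger AMFE = more stable.
   Sequence features are bp % (percentage of nucleotides engaged in base
   pairs), (A-U) % (percentage of base pairs that are strict A-U), and
   nucleotide composition. G-U wobbles count toward bp % but are excluded
   from the (A-U) % numerator; this strict reading shifts (A-U) % values and
   is therefore stated prominently. bp % uses the whole sequence as its
   denominator (stem-only is a plausible alternative; the difference is a
   constant factor per record and does not change orderings).

2. **Element decomposition.** Each hairpin is partitioned into five elements:
   overhang (unpaired ends outside the outermost pair), first stem (the
   maximal run of stacked pairs containing the outermost pair), interior
   loops (all other unpaired positions between helices — internal loops and
   bulges pooled, both strands counted), interior stems (all remaining paired
   positions) and the terminal loop. Structures with zero pairs or more than
   one hairpin loop are disregarded as non-hairpin. Per element we report the
   length ratio (element length / L; the five ratios sum to 1) and the U
   ratio (U count / element length), the latter only for the four stem/loop
   kinds — overhangs are usually too short for a meaningful U ratio — and
   only for non-empty elements (absent, never 0/0).

   *Open boundary:* where the first stem ends is under-determined when the
   basal helix is interrupted; we use the simplest testable rule (any
   interruption — bulge or internal loop — ends the first stem). An
   alternative that tolerates bulges would move nucleotides from
   interior-stem to first-stem but leaves their sum fixed.

3. **Conservation classification** by dual constraint. First, the window
   rule: a record is window-conserved when some window of exactly 15
   consecutive positions inside the hairpin stem region has an arithmetic
   mean conservation score ≥ 0.9 (inclusive). The stem region defaults to
   the full span between the outermost paired bases (`stem_region_mode:
   span`); restricting windows to paired positions only is available as
   `paired` since the original definition is ambiguous. Second, the family
   check: M denotes the number of taxonomic families in which the record's
   miRNA family occurs. Non-conserved records with M = 1 form S_n;
   window-conserved records with M of 5–9, 10–19 and ≥ 20 form S_c1, S_c2
   and S_c3; everything else (conserved with M < 5, non-conserved with
   M > 1, or no family data) is excluded. Finally any (species, group) set
   with fewer than 5 members is dropped from comparisons (members flagged,
   not deleted).

4. **Statistics.** Per species and metric, each conserved set is compared
   with S_n by a two-sided Welch t-test (means; Welch–Satterthwaite df) and
   a two-sided variance F-test (p = 2·min(tails), capped at 1). P-values are
   Benjamini–Hochberg adjusted within each metric across all of its pairwise
   comparisons (pooling species); adjusting per species instead is a
   documented alternative and generally more conservative per family.
   Normality is assessed by a Lilliefors test. Extreme-stability labels
   (ultra stable / unstable) mark records strictly above the 90th / strictly
   below the 10th AMFE percentile per species. The T1/T2 partition takes the
   10th and 90th AMFE percentiles of the pooled most-conserved set S_c3 and
   splits non-conserved records into S_n_u (< T1), S_n_m (T1 ≤ AMFE ≤ T2,
   boundaries inclusive) and S_n_s (> T2); conserved records inside the
   closed band form S_c_m. Pooled cross-species means are sample-size-
   weighted means of per-set means; the same aggregation functions accept
   published summary tables (the bundled
   `reference_group_summaries.tsv`) and internally computed summaries.

## Numerical conventions

- Percentiles: linear interpolation between order statistics
  (`numpy.percentile`, method `linear`); `nearest` (classical nearest-rank)
  is available because T1/T2 shift slightly under it.
- Sample SD uses the n−1 denominator everywhere.
- Welch with two zero-variance samples: p = 1 if means are equal, else 0.
  F-test with zero denominator variance raises.
- Lilliefors p-values are Monte Carlo: the fraction of `mc_reps` (default
  10,000) standard-normal samples of the same n whose D statistic is at
  least the observed one, under a fixed seed — simpler to verify and exactly
  reproducible, unlike closed-form approximations. The null distribution is
  cached per (n, reps, seed).
- The window-rule threshold comparison is inclusive and guarded by a 1e-12
  tolerance against float accumulation in the running mean.
- Ties at extreme-stability thresholds are *not* extreme (strict
  inequalities), so an all-equal sample has no extremes.

## Synthetic populations

The generator is structure-first: element sizes are sampled (overhangs 0–5 nt
per side, basal helix 4–10 bp, 1–3 interior helices of 3–8 bp separated by
interior loops of 0–3 nt per side with at least one unpaired nucleotide,
terminal loop 3–9 nt), the dot-bracket is assembled from them, and
nucleotides are filled in afterwards (pair classes G-C / A-U / G-U by group
weights, unpaired bases by group composition weights). Every record's element
decomposition, pairing statistics and conservation label are therefore known
exactly by construction — no folding step, no stochastic leakage. Records
meant to be conserved carry a planted block of ≥ 15 scores ≥ 0.92 inside the
stem span over a 0.2–0.7 background; non-conserved records have every score
≤ 0.85, so the window rule recovers planted labels perfectly.

Energies: by default a record's MFE comes from a deliberately small
nearest-neighbour evaluator (per-pair strengths 3.2 / 1.1 / 0.5 kcal/mol for
G-C / A-U / G-U; a stack contributes minus the mean strength of its two
pairs; hairpin loops cost +4.0, interior loops +1.2 + 0.3 per unpaired nt).
Its only contracts are determinism and monotonicity (stronger pairs ⇒ lower
energy); its absolute values are not comparable to a full Turner-parameter
fold and are never presented as such. Because a toy energy cannot reproduce
specific population-level AMFE means and SDs, a group may instead declare
its AMFE distribution directly (`amfe_mean` / `amfe_sd`, a normal truncated
at 5 kcal/mol per 100 nt); the `table1-like` preset uses this to plant the
observed study-population structure — per-species group sizes
(132/60/66/33, 108/63/75/39, 21/4/40/19; the 4-member chicken S_c1 cell
deliberately exercises the minimum-set-size drop) with AMFE means ≈ 41–45
and SDs ≈ 5–15, wider in non-conserved sets — and the `null` preset plants
identical distributions in every group for calibration. Conserved groups get
U-enriched unpaired composition and a higher A-U pair weight, non-conserved
groups the reverse, mirroring the observed composition contrasts.

What the generator does *not* emulate: folding-consistent energies (the
structure is planted, not predicted), sequence homology within families,
correlated conservation between paralogs, species-specific base composition,
and non-hairpin precursors. Passing recovery tests therefore demonstrates
the pipeline's correctness on populations whose ground truth is known, not
the biological conclusions' robustness to real miRBase/PhastCons data.

Reproducibility: one global seed drives a hierarchical
`numpy.random.SeedSequence` stream with one child per record, so a record is
reproducible regardless of generation order; identical config + seed gives
byte-identical pipeline outputs.

## Problem sizes

The bundled analyses run at the study-population scale (656–660 records per
synthetic population, ~60–120 nt each). Calibration suites use 2,000 null
replicates (Welch/F/Lilliefors, with a shared 20,000-replicate Monte Carlo
null for the Lilliefors critical value), 500 replicates for the power check
and 40 full null populations for the end-to-end false-positive rate; the
exhaustive structure-enumeration oracle is limited to sequences ≤ 16 nt.

## Known limitations

- The Nussinov routine maximises pair count, not free energy; it is an
  oracle for structure handling, not a folding engine.
- Bulges and internal loops are pooled; analyses that distinguish them need
  a finer element model.
- The F-test's type-I control is exact only under normality — which is why
  the battery carries the Lilliefors check alongside it.
- Duplicate pre-miRNAs (multiple genomic copies) are kept; de-duplication
  policy is left to the user.
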