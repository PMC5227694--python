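# Methods

## The question and the statistical design

Bottom-up proteomics can identify which proteins carry methionine sulfoxide
(MetO) under oxidative stress and which sites are phosphorylated, but it
cannot observe both modifications on the same molecule. `metophos` therefore
treats crosstalk as a question about *spatial statistics of site catalogues*:
if oxidation of methionines near phospho-acceptors is selective rather than
random, then (i) sulfoxidized proteins should be enriched in other PTMs
beyond what protein abundance explains, (ii) oxidized methionines should sit
closer to phosphosites than non-oxidized methionines in the same proteins,
and (iii) specific offsets inside kinase recognition windows (notably P+1
and P+4, hydrophobic specificity-determinant positions) should concentrate
MetO. Each analysis reduces to an observed statistic plus an empirical null
built by resampling.

## Empirical nulls and p-values

All resampling nulls draw without replacement within a sample and
independently across samples. P-values use the add-one estimator

    p = (1 + #{null values as or more extreme}) / (1 + n_samples)

which is never exactly zero; when no null value reaches the observation the
result carries `is_bound = True` and should be read as "p < 1/n_samples".
Test-scale runs default to 10⁴ samples; `n_samples` is configurable to 10⁶
for publication-scale runs.

Two nulls admit an exact shortcut used by default: the uniform overlap null
(the intersection count of a uniform without-replacement sample is
hypergeometric) and the acceptor-resampling null (the mean of a sampled set
of small-integer window counts depends only on the multivariate-
hypergeometric tally of count values). Both shortcuts sample the *same
distribution* as materializing the index samples; the direct sampling path
is retained (`method="count"`) and the suite verifies the two paths agree by
a KS test.

### Abundance-matched sampling

Detection of PTMs by mass spectrometry is strongly abundance-biased, so the
co-occurrence analysis is repeated with nulls matched to the target set's
abundance distribution: quartile boundaries are computed from the target's
abundances; each null sample draws a quarter of its members from pool
proteins falling in each quartile range. Ranges are closed on the left and
open on the right (last range closed); a pool protein whose abundance equals
an internal boundary is assigned to the lower stratum; when the target size
is not divisible by 4 the remainder is allocated one per stratum from the
lowest quartile upward. Each sample's mean log₁₀ abundance and a KS
comparison against the target distribution are recorded as matching
diagnostics. Target proteins without abundance data cannot be matched and
must be dropped by the caller (the pipeline drops and logs them).

## Distances, windows, clusters

- Distance is |Δposition| in residues (1-based coordinates), not a count of
  intervening residues. "Less than 7 residues away" is implemented strictly
  (distance ≤ 6); the inclusive variant is a flag.
- A methionine enters a per-site-kind comparison (pSer, pThr, pTyr, any
  phosphosite, non-phosphorylated acceptor) only when the protein carries at
  least one site of that kind; exclusions go to a coverage log rather than
  being coded as infinite distances. Distance analyses are restricted to
  phosphoproteins.
- Window counts cover offsets ±1..±7 around an acceptor, truncated at the
  termini; the centre slot is excluded. A methionine appearing in the
  windows of several acceptors is counted once per window (windows are
  independent observations of their acceptor).
- Positional profiles use offset-specific denominators (windows where the
  offset falls outside the chain are excluded from that offset's
  denominator), so terminal sites do not deflate frequencies. MetO density
  is reported per 500 phosphosites. The control band is mean ± SD of the 14
  per-offset control frequencies pooled across offsets; per-offset control
  frequencies are also returned.
- Phosphosite clustering counts phosphosites with |Δ| ≤ radius, default
  radius 10 (a 21-residue interval); the half-window reading (radius 5) is a
  parameter away.

## Curation

Sulfoxide site tables may carry a per-site oxidized fraction; the curation
filter keeps sites with fraction ≥ 0.20. The boundary is inclusive and the
threshold configurable, because exclusion of "below 20 %" oxidation leaves
the boundary case unstated; rows with no recorded fraction are ambiguous and
dropped with a warning. Site rows that disagree with the sequence (unknown
accession, residue mismatch, position beyond the chain) are dropped and
counted rather than aborting the load, so partial site tables remain usable.

## Kinase-motif decision tree

The five rules and their order are fixed (see README); first match wins, and
the order matters — ≥5 acidics in P+1..P+6 pre-empts a basic residue at P−3.
Rule ranges are inclusive. Windows truncated at protein termini are padded
with `-`, and a padding slot never satisfies any residue test; the tree is
total over all legal windows (verified exhaustively for single-rule
constructions and on 10⁴ random windows against an independent re-statement
of the rules). By default only phosphoserine windows are classified;
`allow_thr=True` extends the tree to threonine centres.

## Structures

Spatial distances use fixed atoms: Met SD, Ser OG, Thr OG1, Tyr OH;
alternate locations resolve to the highest occupancy. Residues missing their
required atom are excluded and counted — the "unresolved target" filter.
Only intra-chain distances are computed, and PDB numbering is shifted into
sequence coordinates via a per-structure mapping file (`accession pdb_id
chain offset`). DSSP output files are parsed (never recomputed); a blank
structure column reads as coil. Sequence-distance analyses of the structured
subset delegate to the exact whole-proteome code path, which a test asserts.

## The synthetic generator

`SimConfig` defaults encode the observed rates of the curated stress
dataset: methionine at 2.3 % of residues inside otherwise human-like
composition; per-acceptor phosphorylation 24.9 % (Ser), 15.5 % (Thr), 22.8 %
(Tyr); baseline per-Met oxidation 6.7 %; oxidized fractions uniform on
[0.2, 1] so the default curation filter is the identity on synthetic data.
Protein length follows a shifted negative binomial (mean 350, dispersion 6,
minimum 30) and abundance a log-normal (ln-scale μ = 9.2, σ = 2.3, i.e.
median ≈ 10⁴ arbitrary units spanning several decades) — laws chosen once as
realistic for a mammalian cell-line proteome. Ubiquitylation/acetylation are
per-protein Bernoulli flags (base rates 0.45 / 0.35) realized as a site on a
random lysine.

Planted effects:

- **Proximity effect** on the odds scale: a methionine within
  `proximity_radius` (default 7) of a phosphoserine is oxidized with
  probability `odds/(1+odds)` where `odds = proximity_odds · p₀/(1−p₀)`.
  Logit-additivity makes the effect compose with any baseline rate.
- **Positional boost**: the phosphorylation probability of a serine with a
  methionine at given offsets is multiplied (capped at 1), planting
  offset-specific Met–phosphosite coupling.
- **PTM correlation**: `ptm_corr_odds` shifts the ubiquitylation/acetylation
  odds of proteins carrying at least one MetO.

One root `SeedSequence` per run; every protein draws from its own spawned
sub-stream, so outputs are byte-identical under a fixed seed and single
proteins can be regenerated in isolation. Toy structures are loosely
self-avoiding random walks with 3.8 Å Cα steps, a pseudo side-chain atom
2.0 Å off the backbone, and DSSP codes drawn in geometric-length runs; they
provide geometry with known ground truth, not realistic folds.

What the generator does **not** emulate: domain architecture and sequence
autocorrelation, kinase-specific motif preferences, peptide-level detection
bias (flyability), shared evolutionary history between proteins. Passing
calibration and recovery tests on this generator therefore shows the
*statistics* behave as designed — uniform p-values without effects, high
power at the planted effect sizes — not that real proteomes satisfy the
i.i.d. assumptions.

## Calibration and recovery studies

With all effects neutral, the empirical p of each analysis is checked for
uniformity by its rejection rate at α = 0.05 over 500 simulated replicates
(2,000 resamples each); the acceptance band is ±2 binomial SEs around 0.05.
Study sizes per replicate: the co-occurrence calibration simulates 2,000
proteins (mean length 150) because the overlap proportion is discrete — on a
small pool the add-one estimator is visibly conservative at the 5 % level
for reasons of granularity alone; the distance-permutation and
window-resampling calibrations use 150 proteins (mean length 200), their
statistics being means over hundreds of sites and hence effectively
continuous. Recovery uses 200 replicates of 300 proteins: oxidation odds ×4
near phosphoserines must be detected by the two-proportion comparison in
>80 % of replicates, and a ×3 phosphorylation boost for serines with Met at
P+1/P+4 must put those two offsets at the top of the MetO positional profile
in >80 % of replicates. These sizes complete in minutes on one CPU and are
the package's declared test scale.

## Enrichment

Upper-tail hypergeometric p per term, Bonferroni-corrected over the terms
actually tested (terms annotating zero background proteins are skipped and
excluded from the correction denominator). Fold enrichment defaults to the
ratio of proportions (k/n)/(K/N), which is scale-free; the literal count
ratio k/K is available behind `literal_fold=True`. No GO-DAG propagation is
performed — annotation closure is the caller's responsibility.

## Known limitations

- No isoform/variant coordinate mapping; site tables must use the same
  sequence coordinates as the FASTA supplied.
- Only abundance is modelled as a detection confounder; other biases
  (peptide length, enrichment chemistry) are out of scope.
- The two-proportion test is the standard Yates-corrected chi-square (as in
  R's `prop.test`); KS p-values are asymptotic.
- Multi-chain structures contribute only the mapped chain.
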