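# Methods

## The measurement model

A diced-crown experiment quantifies peptides at each of `L` sample blocks
(locations). The pipeline models each protein `i` as having a
stage-structured mean log peak area `μ_i(s)` over the stage vocabulary
{secretory, early_maturation, late_maturation, erupted, DEJ, dentin, bone};
every peptide `j` of the protein responds with a fixed offset `b_ij`
(ionization efficiency, length, charge-state distribution), and each
observation carries multiplicative log-normal noise:

```
area_ijl = exp( μ_i(stage(l)) + b_ij + ε_ijl ),   ε_ijl ~ N(0, σ²)
```

Observations below a fixed detection threshold are left-censored (missing),
which is what the white space in real peptide maps represents: absence of
evidence at the detection limit, not missing-at-random.

The synthetic generator (`synthgrid`) draws from exactly this model. Its
defaults are the study conditions the pipeline was designed around:

- **21 locations** — 20 tooth blocks on two molars (an unerupted M3 spanning
  secretory → maturation stages, a partially erupted M2 adding erupted
  enamel) plus one alveolar-bone sample; block volumes ~ N(2.3, 0.4²) mm³,
  matching the reported mean block volume, truncated at 0.2 mm³.
- **60 proteins in six abundance classes** (plus the four marker parents):
  enamel-matrix (secretory-high), maturation, DEJ, cuspal, skeletal
  (bone/dentin) and flat background, in rotation, with stage contrasts of
  2–4 natural-log units — one to two orders of magnitude, the scale of
  contrast enamel matrix proteins actually show between secretory and
  mature enamel.
- **Noise** `σ = 0.3` (≈ 30% CV, typical for label-free peak areas) and
  peptide response SD 0.5; detection threshold `e^10`, so low-abundance
  stage/protein combinations are partially censored while high-abundance
  ones never are.
- **Phospho-occupancy profiles** per marker are stage-based templates in
  [0.1, 0.9]: amelogenin markers most phosphorylated in secretory/early
  maturation enamel, the ameloblastin marker the reverse, the enamelin
  marker high everywhere. Keeping profiles off the {0,1} boundary keeps the
  minor form above the detection limit, so recovery error measures the
  estimator rather than censoring.

Randomness uses one global seed with per-protein substreams
(`default_rng([seed, protein_index])`), so enlarging a configuration never
reshuffles existing proteins' draws.

What the generator does **not** emulate: chromatography and spectra,
identification error (all simulated identifications are correct, with
significance scores drawn well above threshold), shared (non-unique)
peptides, cross-block smearing/contamination, and any volume dependence of
peak areas — areas are generated volume-free, so the pipeline's volume
normalization acts on them as a small per-column rescaling rather than a
correction. Passing tests therefore demonstrate correctness of the
analysis operations and calibration of the statistics under the stated
model, not robustness to identification error or contamination in real
data.

## Quantification

Top-3 abundance sums the three largest pooled unique-peptide areas per
protein × location (pooling repeat observations of a sequence first; ties
at rank 3 broken lexicographically for determinism). Top-3 selection is
**local** (per location): the three most abundant peptides at that block,
not a globally fixed trio. Volume normalization multiplies each column by
`V_ref / V_l` with `V_ref = 2.14 mm³`, so equal tissue concentrations in
different block sizes map to equal values. The canonical order is
top3 → volume_normalize → {percent | natural log}; it is fixed and
regression-tested (volume normalization is per-column, percent scaling
per-row; they do not commute with the cell-wise log).

Percent scaling exists in two variants: per tooth crown (each row scaled to
its within-crown maximum — the visualization convention, written to
`abundance_percent_per_tooth.tsv`) and global (one maximum per row across
all locations, written to `abundance_percent.tsv`). The statistics stages
consume the **global** variant: per-crown scaling makes the same protein's
values incomparable across teeth (a protein peaking in M3 secretory enamel
would get 100% at its much lower M2 maximum too), which distorts any
distance computed between locations of different teeth. The log transform
maps zeros to missing (audited) and rejects negatives.

## Phospho-occupancy

Occupancy at a location is `P/(P+NP)`: summed area of marker-sequence
records carrying Phospho at the marker site over the summed area of both
pools. Records with Phospho elsewhere in the peptide match neither pool and
are audited; other modifications are ignored for matching; charge states
and repeat observations sum by sequence identity. The ratio is invariant to
any per-location rescaling, so it is computed from raw or volume-normalized
areas interchangeably (asserted by test). A missing pool counts as zero
when the other form was observed; the ratio is undefined only where
neither form was seen. An optional flag additionally divides by the
crown-wide pooled ratio; it is off by default, the per-location ratio being
the directly interpretable stoichiometry.

Marker validation digests the parent in silico — cleavage C-terminal to
K/R, the proline rule switchable, ≤ 2 missed cleavages, matching the
identification search settings — and confirms the marker is a producible
tryptic product. Digestion is implemented directly (products carry start
offset and missed-cleavage count, both needed for reporting) and is
cross-checked in tests against both a brute-force substring enumerator and
an independent proteomics library. The bundled parent sequences are
constructed synthetic stand-ins (marked as such in the FASTA) that embed
each marker at a tryptic-producible position; real analyses should supply
the organism's reference FASTA.

## Statistics

**Missing values.** PCA, clustering and testing require complete data; the
default policy imputes zeros on the percent scale (absence = not detected,
audited), with row deletion available behind a flag.

**Clustering.** Locations are clustered on Euclidean distance; the linkage
method is configurable {single, complete, average, ward} with **average**
as default — a middle ground that does not chain like single linkage and
does not require the variance assumptions of Ward. The k = 5 cut reflects
the five qualitative location groups a diced developing crown presents
(secretory, maturation, DEJ, cuspal/erupted, non-enamel); clusters are
named by majority a-priori stage, ties broken toward the earlier
developmental stage.

**Permutation ANOVA.** Per protein, the one-way F statistic across named
enamel groups (NonEnamel excluded by default); the null is built by
uniformly permuting group labels. With `B = 4999` permutations (default),
`p = (1 + #{F* ≥ F}) / (1 + B)`, so the smallest attainable p is 2·10⁻⁴;
when the number of distinct label arrangements is ≤ B the null is
enumerated exhaustively and `p = #{F* ≥ F}/N` including the identity.
Degenerate case: zero within-group variance with nonzero between-group
variance sets F = +∞, which compares cleanly inside the permutation test.
Permuted F values are compared with a relative tolerance of 10⁻⁹ so
floating-point jitter in algebraically tied statistics cannot flip counts.
B = 4999 keeps p granularity (2·10⁻⁴) below the BH threshold resolution at
the problem sizes involved while staying fast; per-protein permutation
seeds derive from the global seed.

**FDR and directions.** BH step-up (via statsmodels, with a brute-force
definitional oracle in the tests); direction per named group is
higher/lower versus the pooled mean of the other groups' values, exact ties
neutral, reported only for BH-significant proteins.

**Decile pre-filter.** "Drop the least abundant decile of a group" uses the
nearest-rank convention: with `k = ⌈percentile·n/100⌉`, the cutoff is the
(k+1)-th smallest group mean and values strictly below it are removed —
exactly k proteins when means are distinct, none when all are equal (ties
at the cutoff are retained, the conservative choice).

**Over-representation.** One-sided hypergeometric tail per annotation term
against a user-supplied background, BH-adjusted; terms with fewer than two
hits are skipped, set members absent from the background are audited and
ignored. This is a generic, self-contained enrichment test; it does not
reproduce any particular web service's annotation databases or scoring
variants.

## Problem sizes

The shipped defaults (60 + 4 proteins, 21 locations, B = 4999) run the full
pipeline in seconds. The acceptance checks use 1000 null proteins at
B = 999 for calibration, 500 proteins (10% true effects, effect = 2 noise
SDs) for FDR control, and 10–20 seeded replicate runs for recovery rates —
sizes at which Monte-Carlo error of the measured rates is a few tenths of a
percent to a few percent, small against the margins being asserted.

## Known limitations

- Uniqueness of peptides is dataset-wide; razor-peptide assignment is out
  of scope, and significance is thresholded per protein as carried on
  input, never recomputed from spectra.
- The permutation test is univariate per protein; no multivariate variant.
- Exchangeability of locations under the null ignores spatial
  autocorrelation between adjacent blocks; p-values are calibrated under
  the simulator's independent-noise model.
- Direction calls compare one group against the pooled others; subtler
  patterns (gradients along a crown) are not classified.
- The enrichment test treats annotation terms independently; no term
  hierarchy or redundancy handling.
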