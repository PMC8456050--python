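# Methods

## Model and assumptions

The method rests on the connectivity-mapping hypothesis: a compound whose
transcriptional response is anticorrelated with a disease expression
signature is a candidate for reverting the disease phenotype. Two
assumptions are added on top:

1. **Pathway level beats gene level.** Signatures of the same compound
   measured in different cell lines or at different doses share little at
   the individual-gene level (the packaged worked example: two instances of
   the same anchor drug share only 6.4% of up- and 13.6% of down-genes),
   but their pathway enrichment profiles correlate strongly. All matching
   is therefore done on vectors of per-pathway enrichment z-scores.
2. **Synergy by complementary reversal.** If an anchor drug reverses part
   of the disease pathway signature (ACPs) but leaves another part
   co-dysregulated (CPs), a partner that specifically reverses the CPs
   should act synergistically: the pair covers the full dysregulated set.

### Enrichment score

For signature *c* (50 up- and 50 down-genes) and pathway *p*, the overlap
count `N_{c,p}` per direction is standardized as
`z = (N − μ_p)/σ_p`, with `μ_p, σ_p` the sample mean/sd of the overlap of
20,000 random 50-gene sets drawn uniformly without replacement from the
profiling platform's gene universe. Because a random signature is
distributed exactly like the background draws, its z-scores have mean 0 and
sd 1 by construction — verified empirically in the tests. The Monte-Carlo
estimates agree with the closed-form hypergeometric mean/sd, which the test
suite uses as an independent oracle (the analytic law is deliberately *not*
used in the implementation; the stochastic background is the method).

The two directional scores are combined into one signed value per pathway,
`z_net = z_up − z_down`. The combination rule is a documented design
choice: reversal semantics require a signed quantity (a pathway enriched in
the disease's up-genes and in a compound's down-genes must come out with
opposite signs), and `z_net` is the simplest such combination. Both
directional maps are retained in `PathwaySignature`, and the ranking stage
accepts a `directional=True` flag that correlates the concatenated
per-direction scores instead, for sensitivity analysis.

Pathways with `σ_p = 0` (degenerate, e.g. a pathway covering the whole
universe, or empty within it) are excluded from signatures and recorded in
`PathwaySignature.excluded` rather than producing infinities.

### Backgrounds and universes

One background per (universe, set size) is shared across all compounds and
both directions: the background law depends only on the draw length, so
per-compound backgrounds would be statistically identical and 20,000×
costlier. Signatures shorter than the standard 50 require a dedicated
background of matching length (`enrich` refuses mismatched lengths rather
than silently padding). Disease signatures are standardized against the
expression assay's gene universe (configurable via `assay_universe`), while
compound signatures use the compound platform's universe, mirroring the
different measurement platforms.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `signature_size` | 50 | genes per direction in every signature |
| `n_draws` | 20,000 | random sets per background |
| `threshold_disease` | 2.58 | two-sided z cutoff (normal p < 0.01) for selecting disease pathways |
| `threshold_compound` | 2.58 | anchor-side strength needed to call a selected pathway CP or ACP; `0` reproduces a pure sign rule |
| Loewe solver | 1e−12 bracket tolerance, ≤200 iterations | bisection of the dose-equivalence equation on `[max(e0), min(emax)]` |
| synergy summary | plain sum of surface cells | pluggable (`sum`, `mean`, custom weight matrix) |

The anchor-side threshold is a deliberate addition: classifying CP vs ACP by
sign alone lets near-zero anchor scores flip pathways between classes;
requiring the same 2.58 strength routes weak pathways into an explicit
`undetermined` class instead.

## Numerical and procedural choices

* **Gene matching** is exact string comparison after trimming and
  case-folding; alias resolution is data, not method, and is out of scope.
* **Top-n selection** for the disease signature sorts by `(−log2FC, gene)`
  and takes the up list first; the down list is then drawn from the
  *remaining* genes by `(log2FC, gene)`. This makes the two lists disjoint
  by construction and fully deterministic under ties; the only error
  condition is fewer than 2n finite genes.
* **Missing pathways** (σ=0 exclusions) in a compound signature score as
  z = 0 wherever a subset correlation is computed, so every compound is
  scored on the same vector and scores are comparable across a library.
  Subsets with fewer than 3 scorable pathways, or zero-variance restricted
  vectors, yield an undefined score with a recorded reason — never a NaN
  propagated into a ranking.
* **Ties in ranking** are broken by signature id.
* **4PL fits** use bounded least squares parameterized as
  `(e0, emax−e0, ec50, h)` so `0 ≤ e0 ≤ emax ≤ 1` holds by construction.
  GI50/GI90 are solved analytically from the fitted parameters and reported
  as "not reached" when the target inhibition lies outside the fitted
  asymptotes or beyond the tested dose range. A flat response degenerates
  to a constant fit (no error); genuine non-convergence raises an error
  carrying the residuals.
* **Loewe expectation**: the dose-equivalence equation is solved per cell
  by `brentq` on the common invertible effect range; cells whose expected
  effect pins to a bracket edge are clamped and counted in the result's
  metadata. Sham self-combinations recover a zero surface to < 1e−6 on the
  inhibition-fraction scale.
* **Category comparison**: the t-test is one-tailed (combination category >
  single agents), Welch by default with a pooled-variance option, since the
  test flavor behind the published comparison is not documented. p-values
  are reported, not asserted. Compounds annotated with two score types
  (e.g. "Res/Score1") count in both categories — required to reproduce both
  category means. Positive controls are excluded from every category.
* The published text quotes a single-agent Loewe average of 10.15 ± 4.7
  while the corresponding table column averages 10.67; the packaged table
  reproduces the table value and the discrepancy is left unresolved.
* The exact weighting behind the external software's weighted-sum synergy
  score is undocumented; the default summary is the plain cell sum with a
  pluggable weighting interface, and the scoring-category analysis
  consumes the published per-compound summary scores as fixture inputs
  rather than recomputing them from raw plates.

## The synthetic-data generator

`simulate` emulates the *shapes* of the real inputs: a 978-gene landmark
universe, 200 random pathways of 15–25 genes, 50/50 signatures, multi-cell
disease panels, 8×8 checkerboards. Planted structure:

* disease contrasts shift all genes of chosen pathways by ±δ (default 3)
  over N(0,1) noise — at δ = 3 every planted pathway clears |z| ≥ 2.58;
  at δ = 0 the false-positive rate matches the exact hypergeometric tail
  (the nominal 1% per direction is only approximate, because overlap counts
  are small integers and the discrete upper tail at the 2.58 cutoff is
  slightly heavier than normal);
* compound roles (`full_reverser`, `partial_reverser_acp`, `cp_reverser`,
  `res_reverser`, `decoy`) place genes of the targeted pathways into the
  opposing (or matching) signature direction, `effect_strength` (default
  0.9) of each list, the rest uniform filler;
* dose matrices are generated under Bliss-null, Loewe-null (sham
  self-combination) or uniform-boost models with optional Gaussian noise.

What the generator does **not** model: L1000 inference-gene structure,
correlated gene expression noise, realistic pathway overlap topology, batch
effects, or dose–duration response of signatures. Passing recovery tests
therefore demonstrate the *scoring machinery* is correct and discriminating
under clean planted signal, not that the method's effect sizes transfer to
real LINCS/GEO data.

### The recovery experiment and its limits

The canonical experiment (`run_recovery_trial`) plants 6 up + 6 down
disease pathways; the anchor reverses 4 (ACPs) and correlates on 8 (CPs);
a 6-pathway resistance subset of the CPs is planted only in the focal line.
Over 50 seeds at the defaults, the full reverser takes rank 1, the CP
reverser scores Score1 ≤ −0.8, and the resistance reverser uniquely
minimizes the Res-score among its competitive set (anchor + decoys) in 100%
of seeds. Uniqueness is judged against that competitive set because the
full- and CP-reversers revert supersets of the resistance pathways by
construction and legitimately tie near −1 there.

One property cannot hold as sometimes stated for screens of this geometry:
that every random decoy's Score1 stays within (−0.3, 0.3) in ≥95% of runs.
A decoy's score is a Pearson correlation of independent noise against the
disease z-vector over the n CP pathways; under independence its null sd is
≈ 1/√(n−1). A 50-gene disease signature at the 2.58 cutoff can support at
most ~10–25 quasi-independently significant pathways (each needs several of
the 50 genes), so the per-decoy sd is ≥ 0.2 and the ±0.3 band is exceeded
far too often (measured: 60% of decoy scores in-band at n_CP ≈ 9). The
*mean* decoy score is unbiased at zero and the planted reversers separate
from decoys by a wide margin; the band is a property of the Pearson null
distribution, not an implementation defect. The corresponding acceptance
test is kept as specified and is expected to fail.

## Problem sizes used by tests and the acceptance script

Unit tests run on 300–1,000-gene universes with 40–50 pathways and 1,500–
4,000 background draws; the calibration and recovery checks use the full
20,000 draws, a 1,000-gene universe for the hypergeometric comparison, and
50 generator seeds for recovery rates. The complete suite runs in well
under a minute of CPU.

## Known limitations

* Pearson correlation on small pathway subsets (< ~10) is noisy; the
  package reports the subset size next to every score so users can judge.
* The Res-score is undefined when no CP pathway is focal-specific; the
  pipeline reports the empty set rather than inventing a fallback.
* Scores of compound instances are never aggregated across cell lines,
  doses or durations — instances are ranked separately, as in the source
  screens.
* GMT parsing follows the common dialect (name, description, genes);
  probe-to-gene collapsing and normalization of expression matrices are out
  of scope: inputs are assumed to be per-gene log2 fold changes.
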