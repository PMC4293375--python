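# Methods

## The association model

Every (marker, trait) pair is fit by simple linear regression of the
trait on allele dosage — no covariates inside the scan itself.
Covariate adjustment is a separate, explicit step (`adjust`): traits
are residualized on the covariates by OLS and optionally
inverse-normal transformed *before* scanning. This split keeps the
inner loop a pure two-variable fit, which is what makes scanning
millions of marker×trait pairs tractable, and it matches how large
cohort pipelines typically separate phenotype preparation from the
scan.

Dosage is the expected effect-allele count p_AB + 2·p_BB from the
genotype probability triple. Probabilities are **not** renormalised:
imputation output encodes genotype uncertainty in triples that may sum
below 1, and renormalising would silently overstate confidence. A
triple summing below a completeness threshold (default 0.1, exposed as
a flag) is treated as a missing genotype.

Degrees of freedom are n_used − 2 per pair, recomputed under
missingness — correctness is preferred over the shortcut of a fixed
per-marker df. Pairs with fewer than 3 complete observations, a
monomorphic dosage, or zero residual variance are flagged untestable
or degenerate and routed to a side channel, never to the results
stream; runtime filters (minimum minor allele count, maximum p,
maximum SE, minimum |β|) therefore act only on well-defined fits. The
p-value threshold is inclusive (p ≤ p_max) so row counts are exactly
reproducible. MAC is computed on fractional dosages without rounding,
since dosages are expectations.

### Multi-trait pass structure

The scan streams the GEN file once. Per marker, sufficient statistics
are accumulated per *distinct trait-missingness mask*: all traits
sharing an observation pattern share a single pass over the dosage
vector (one Sxx, vectorised Sxy/Syy across the block). A fully
observed trait matrix costs one pass regardless of trait count, which
is the mechanism that makes ratio-trait scans (thousands of derived
traits) cheap.

### P-value lookup tables

Exact two-sided Student-t tails are computed in log space
(`t.logsf`), so p-values remain representable down to ~1e-300.
The interpolated mode precomputes −log10 p on a |t| grid
(default step 0.01 up to |t| = 40, one cached table per distinct df)
and linearly interpolates in −log10 space; |t| beyond the grid falls
back to the exact tail. −log10 p is nearly linear in |t| at this
resolution, and the property suite verifies agreement with the exact
tail within 1% relative everywhere on the grid for df ∈ {8, 98, 998}.
The grid extent and step are package choices validated against exact
mode; exact mode remains the default.

## Ratio traits

For n selected traits, each unordered pair {i < j} yields one ratio
trait trait_i / trait_j named `<num>_DIV_<den>`; the count is
n(n−1)/2 (6216 for 112 traits). One direction per pair is the
default — A/B and B/A carry equivalent signal under log-scale
analysis — with a flag for both directions. Ratios are computed on the
raw scale; an optional flag analyses log(ratio) instead. A ratio value
is missing wherever either component is missing or the denominator is
zero. The `_DIV_` name encoding is deliberately lossless: it is the
join key by which the RS stage re-attaches single-trait p-values, so
no side-table needs to survive between pipeline stages.

## Adjustment and transformation

Residualization is complete-case OLS on [intercept | covariates];
rows missing in the trait or any covariate stay missing, and a
rank-deficient design raises an error naming the collinear columns.
The inverse-normal transform uses Blom ranks, Φ⁻¹((r − 3/8)/(m + 1/4))
with average ranks for ties — the standard GWAS choice; it is
undefined (error) for constant traits.

## The Reliability Score

RS = min(p_num, p_den) / p_comb, computed in log10 space because
genome-wide p-values routinely sit near the double-precision underflow
boundary. RS > 1 iff the ratio's p beats both single-trait p's. The
annotation stage never silently drops a ratio row whose single-trait
partner was filtered upstream; such rows go to an explicit unmatched
list. Per-marker summaries (smallest p or largest |β|) break ties by
lexicographic trait name for determinism.

## Synthetic data

The fixture generator draws Hardy–Weinberg hard-call genotypes at
per-marker MAF uniform in a configured range (default 0.05–0.5),
writes them as valid GEN/SAMPLE files, and builds traits as planted
linear combinations of dosages plus Gaussian noise, with optional
genotype and phenotype missingness. A manifest file stores the exact
dosage matrix and planted effects so parsers and scans can be checked
against ground truth. Everything is a pure function of the seed.

What it does **not** emulate: linkage disequilibrium between markers,
imputation uncertainty (fixtures are hard calls; the parser's handling
of soft triples is tested separately), population structure, and
non-Gaussian trait noise. Passing tests on these fixtures therefore
demonstrate numerical and plumbing correctness, not robustness to
confounding in real cohorts.

### The two-scenario RS validation

The simulation that validates RS as a model-selection score generates,
per replicate, a biallelic marker g (n = 1000, MAF 0.3) and two traits
under one of two models:

* **ratio scenario** — log A = z + (β/2)g + ε₁,
  log B = z − (β/2)g + ε₂, with a shared latent scale
  z ~ N(0, 1) and ε ~ N(0, 0.3²), β = 0.4. The shared factor cancels
  in A/B, so the ratio association is strong while each single trait
  is diluted — the common-scale-cancellation argument for metabolite
  ratios, made concrete.
* **linear scenario** — A = βg + ε₁, B = ε₂ independent: the marker
  affects A but adds nothing through the ratio.

Each replicate runs the full pipeline (OLS of A, B and A/B on g; RS
from the three p-values) and is classified "ratio model" iff RS > 1.
Accuracy is reported per scenario and overall (500 replicates per
scenario by default, seconds of runtime). The generative equations and
all parameters are exposed in `SimulationConfig`; the defaults above
are the package's stated study conditions, and with them the RS rule
recovers the generating model in effectively all replicates,
comfortably above the 95% level the score is meant to clear.

## Numerical and design notes

* Negative residual sums of squares from rounding are clamped at zero
  before the variance estimate.
* GEN dialect: five metadata columns by default; a leading chromosome
  column is supported behind a flag. Delimiters are any run of
  whitespace. gzip input is detected by magic bytes, not file name.
* The SAMPLE reader treats type codes P and C as analyzable continuous
  traits, D as covariate columns, B as binary (excluded from the
  linear scan); the missing token is configurable (default `NA`, with
  `-9` as a common addition).
* Scan outputs are written to a temporary file and atomically renamed;
  a failed run leaves no partial results. Run logs (marker/trait
  counts, emitted/filtered/untestable rows) go to stderr and a
  `.log` sidecar, never into the results stream.
* The results emitted + filtered + untestable always total
  markers × traits; this conservation is asserted in the test suite
  and holds for any chunk size, since chunking affects only I/O.

## Known limitations

Binary traits, dominance/recessive codings, BGEN/VCF input, X-ploidy
handling and multiple-testing correction are out of scope. The scan is
single-threaded; problem sizes in the test suite and validation script
(tens of markers in fixtures, 1000 simulation replicates) are chosen
to exercise every code path while keeping the whole suite in the
tens-of-seconds range.
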