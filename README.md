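# ratioscan

Mass simple-linear-regression association scanning for GWAS, with
automatic pairwise ratio ("combinatorial") traits and a Reliability
Score for ranking ratio-trait hits.

## Who this is for

Analysts running genome-wide association scans of continuous traits —
especially metabolomics studies, where trait *ratios* can proxy
enzymatic conversion rates and associate more strongly than either
component concentration. `ratioscan` streams Oxford GEN/SAMPLE
genotype files (plain or gzipped), tests every marker against every
trait in one pass, generates all pairwise ratio traits on request, and
mines the results afterwards (filtering, per-marker summaries,
reliability scoring).

## The model

For each marker and trait, the *allele frequency test* is simple OLS
of the trait y on the allele dosage x = p_AB + 2·p_BB (expected count
of allele B, the effect allele). Over the n complete (x, y) pairs,
with centred sums Sxx, Syy, Sxy:

    β = Sxy / Sxx
    s² = (Syy − β·Sxy) / (n − 2)
    SE = √(s² / Sxx)
    t = β / SE,  two-sided p from Student t on n − 2 df

P-values come from the exact Student-t tail or, for speed at scale,
from a precomputed −log10 p lookup table on a |t| grid with linear
interpolation (one cached table per distinct df; |t| beyond the grid
falls back to the exact tail).

For a ratio trait A/B the **Reliability Score** compares the ratio's
association to its components at the same marker:

    RS = min(p_A, p_B) / p_{A/B}

RS > 1 means the ratio associates more strongly than either single
trait. Example: p(A) = 10⁻⁶, p(B) = 10⁻², p(A/B) = 10⁻¹⁰ gives
RS = 10⁻⁶/10⁻¹⁰ = 10⁴.

## Worked example

Generate a small synthetic cohort (10 markers, 200 individuals, three
traits with an effect of 0.5 per allele planted on trait1), then scan
raw plus ratio traits and attach Reliability Scores:

```sh
ratioscan simulate-fixture --out fx --n-markers 10 --n-samples 200 \
    --n-traits 3 --beta 0.5 --seed 7
ratioscan scan --gen fx/fixture.gen --sample fx/fixture.sample \
    --out results.tsv --ratios
```

The scan log (stderr and `results.tsv.log`) reports:

```
markers	10
traits	6
rows_emitted	60
rows_filtered	0
rows_untestable	0
```

Ten markers × (3 raw + 3 ratio) traits = 60 tests, none filtered and
none untestable. The results file starts:

```
snp_id	rs_id	pos	allele_a	allele_b	trait	n	eaf	mac	beta	se	t	p
snp1	rs1	1000	A	G	trait1	200	0.34	136	0.5031346692	0.1459185929	3.448050445	0.0006896980359
```

snp1 carries the planted effect: the estimated slope 0.503 per G
allele recovers the simulated 0.5, with p ≈ 7×10⁻⁴ at n = 200.
`results.tsv.rs.tsv` holds one row per (marker, ratio trait) with the
three p-values and the RS; here the ratio traits score RS < 1
(e.g. trait1/trait2 at snp1: RS ≈ 0.002) because the effect is linear
on trait1 alone, so the ratio only dilutes it — exactly what RS is
designed to flag.

Other subcommands: `make-ratios`, `adjust` (covariate residualization
and rank-based inverse-normal transform), `rs`, `summarize`
(strongest trait per marker), `extract` (filter + count). All of this
is equally available as a library (`import ratioscan`).

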