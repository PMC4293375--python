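"""Synthetic genotype/phenotype generation and the RS validation study.

Two jobs live here.

First, a fixture generator: Hardy-Weinberg genotypes at chosen minor
allele frequencies, written as valid GEN/SAMPLE files together with a
ground-truth manifest (the exact dosage matrix and planted effect
sizes), so every parser and scan result can be checked against what
was generated.

Second, the two-scenario simulation that validates the Reliability
Score as a model-selection statistic:

* ratio scenario — the marker acts on the *ratio* of two traits.
  Both traits share a latent scale factor z ~ N(0, shared_factor_sd^2)
  and the marker pushes them in opposite directions on the log scale:

      log A = z + (beta/2) g + e1,   log B = z - (beta/2) g + e2

  z cancels in A/B, so the ratio association is strong while each
  single trait is diluted by the shared variation — the mechanism that
  makes metabolite ratios informative (common-scale cancellation).

* linear scenario — the marker has an ordinary linear effect on one
  trait and nothing else: A = beta*g + e1, B = e2.

Per replicate, the full pipeline runs (fit A, B and A/B against the
dosage, compute RS) and the replicate is classified as "ratio model"
iff RS exceeds a threshold (default 1: the ratio beats the better
single trait).  Accuracy is the fraction of replicates assigned to
their true generating scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assoc import fit_simple_ols
from .gen_io import MarkerRecord, SampleTable, write_gen_file, write_sample_file
from .postrun import reliability_score

__all__ = [
    "TraitSpec",
    "FixtureConfig",
    "SimulationConfig",
    "Fixture",
    "make_fixture",
    "write_fixture",
    "sample_dosages",
    "simulate_ratio_scenario",
    "simulate_linear_scenario",
    "evaluate_rs_classifier",
    "ClassifierReport",
]


@dataclass
class TraitSpec:
    """One simulated trait: y = sum_m beta[m] * g_m + N(0, noise_sd^2).

    ``betas`` is either None (pure noise trait), a scalar applied to
    every marker, or a per-marker array.  ``missing_rate`` knocks out
    phenotype values at random.
    """

    name: str
    betas: float | np.ndarray | None = None
    noise_sd: float = 1.0
    missing_rate: float = 0.0


@dataclass
class FixtureConfig:
    """Recipe for a GEN/SAMPLE fixture with known ground truth."""

    n_markers: int = 10
    n_samples: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotype_missing_rate: float = 0.0
    traits: list[TraitSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.genotype_missing_rate < 1.0):
            raise ValueError("genotype_missing_rate must be in [0, 1)")
        for t in self.traits:
            if t.noise_sd <= 0:
                raise ValueError(f"trait {t.name}: noise_sd must be > 0")


@dataclass
class Fixture:
    """In-memory ground truth for a generated fixture."""

    markers: list[MarkerRecord]
    sample_table: SampleTable
    dosage_matrix: np.ndarray  # markers x samples, NaN = missing
    betas: np.ndarray          # markers x traits (planted effects)
    mafs: np.ndarray           # per-marker simulated MAF
    config: FixtureConfig


def sample_dosages(rng: np.random.Generator, maf: float, n: int) -> np.ndarray:
    """Hard-call dosages under Hardy-Weinberg at the given MAF
    (allele B is the minor allele)."""
    return rng.binomial(2, maf, size=n).astype(float)


def make_fixture(cfg: FixtureConfig) -> Fixture:
    """Generate genotypes and phenotypes with planted linear effects.

    Genotypes are Hardy-Weinberg hard calls at per-marker MAF drawn
    uniformly from ``maf_range``; each trait is the planted linear
    combination of dosages plus Gaussian noise.  Deterministic in the
    seed: identical configs give identical fixtures.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    dosages = np.vstack([sample_dosages(rng, maf, cfg.n_samples)
                         for maf in mafs])
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.genotype_missing_rate
        dosages[miss] = np.nan

    n_traits = len(cfg.traits)
    betas = np.zeros((cfg.n_markers, n_traits))
    values = np.empty((cfg.n_samples, n_traits))
    g0 = np.nan_to_num(dosages)  # missing genotypes contribute no effect
    for j, spec in enumerate(cfg.traits):
        if spec.betas is not None:
            b = np.broadcast_to(np.asarray(spec.betas, dtype=float),
                                (cfg.n_markers,))
            betas[:, j] = b
        y = betas[:, j] @ g0 + rng.normal(0.0, spec.noise_sd, cfg.n_samples)
        if spec.missing_rate > 0:
            y = y.copy()
            y[rng.random(cfg.n_samples) < spec.missing_rate] = np.nan
        values[:, j] = y

    sample_ids = [f"id{i + 1}" for i in range(cfg.n_samples)]
    markers = [
        MarkerRecord(f"snp{m + 1}", f"rs{m + 1}", 1000 * (m + 1), "A", "G",
                     dosages[m])
        for m in range(cfg.n_markers)
    ]
    table = SampleTable(sample_ids, [t.name for t in cfg.traits],
                        ["P"] * n_traits, values)
    return Fixture(markers, table, dosages, betas, mafs, cfg)


def write_fixture(fixture: Fixture, outdir, *, gzip_gen: bool = False,
                  prefix: str = "fixture") -> dict[str, Path]:
    """Write a fixture's GEN, SAMPLE and ground-truth manifest files.

    The manifest is a delimited table: one row per (marker, sample)
    dosage plus a header block of planted betas, enough to reconstruct
    the ground truth without re-running the generator.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_path = outdir / (prefix + (".gen.gz" if gzip_gen else ".gen"))
    sample_path = outdir / f"{prefix}.sample"
    manifest_path = outdir / f"{prefix}.truth.tsv"
    write_gen_file(gen_path, fixture.markers, gzip_out=gzip_gen)
    write_sample_file(sample_path, fixture.sample_table)
    with open(manifest_path, "wt") as fh:
        fh.write(f"#seed\t{fixture.config.seed}\n")
        trait_names = fixture.sample_table.trait_names
        fh.write("#betas\tmarker\t" + "\t".join(trait_names) + "\n")
        for m, marker in enumerate(fixture.markers):
            fh.write("#betas\t" + marker.snp_id + "\t"
                     + "\t".join("%.10g" % b for b in fixture.betas[m]) + "\n")
        fh.write("marker\t" + "\t".join(fixture.sample_table.sample_ids) + "\n")
        for m, marker in enumerate(fixture.markers):
            cells = ["NA" if np.isnan(d) else "%.10g" % d
                     for d in fixture.dosage_matrix[m]]
            fh.write(marker.snp_id + "\t" + "\t".join(cells) + "\n")
    return {"gen": gen_path, "sample": sample_path, "manifest": manifest_path}


# ---------------------------------------------------------------------------
# the two-scenario RS validation


@dataclass
class SimulationConfig:
    """Parameters for the RS model-selection simulation.

    Defaults are the study conditions: 1000 individuals, MAF 0.3,
    marker effect 0.4, latent shared scale sd 1.0, residual sd 0.3,
    500 replicates per scenario, classification threshold RS > 1.
    """

    n_individuals: int = 1000
    maf: float = 0.3
    beta: float = 0.4
    shared_factor_sd: float = 1.0
    noise_sd: float = 0.3
    n_replicates: int = 500
    rs_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 0.5):
            raise ValueError("maf must be in (0, 0.5)")
        if self.shared_factor_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("all standard deviations must be > 0")
        if self.rs_threshold <= 0:
            raise ValueError("rs_threshold must be > 0")


def simulate_ratio_scenario(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One replicate where the marker drives the A/B ratio.

    Returns (g, A, B): log A = z + (beta/2) g + e1,
    log B = z - (beta/2) g + e2 with shared z ~ N(0, shared_factor_sd^2)
    and e ~ N(0, noise_sd^2).  z cancels in A/B.
    """
    n = cfg.n_individuals
    g = sample_dosages(rng, cfg.maf, n)
    z = rng.normal(0.0, cfg.shared_factor_sd, n)
    e1 = rng.normal(0.0, cfg.noise_sd, n)
    e2 = rng.normal(0.0, cfg.noise_sd, n)
    a = np.exp(z + 0.5 * cfg.beta * g + e1)
    b = np.exp(z - 0.5 * cfg.beta * g + e2)
    return g, a, b


def simulate_linear_scenario(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One replicate where the marker has a plain linear effect on A
    only; B is independent noise, so the ratio adds nothing."""
    n = cfg.n_individuals
    g = sample_dosages(rng, cfg.maf, n)
    a = cfg.beta * g + rng.normal(0.0, cfg.noise_sd, n)
    b = rng.normal(0.0, cfg.noise_sd, n)
    return g, a, b


@dataclass
class ClassifierReport:
    """Per-scenario and overall accuracy of the RS > threshold rule."""

    accuracy_ratio_scenario: float
    accuracy_linear_scenario: float
    accuracy_overall: float
    n_replicates_per_scenario: int
    rs_ratio_scenario: np.ndarray
    rs_linear_scenario: np.ndarray


def _replicate_rs(g: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Run the pipeline on one replicate: fit A, B and A/B on dosage,
    return the Reliability Score of the ratio trait."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b == 0, np.nan, a / b)
    p_a = fit_simple_ols(g, a).p
    p_b = fit_simple_ols(g, b).p
    p_r = fit_simple_ols(g, ratio).p
    return reliability_score(p_a, p_b, p_r)


def evaluate_rs_classifier(cfg: SimulationConfig) -> ClassifierReport:
    """Accuracy of RS-threshold model selection over the two scenarios.

    For each replicate of each scenario the three regressions are fit,
    RS is computed, and "ratio model" is declared iff
    RS > cfg.rs_threshold.  A ratio-scenario replicate is correct when
    declared ratio; a linear-scenario replicate when not.
    """
    if cfg.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    rs_ratio = np.array([_replicate_rs(*simulate_ratio_scenario(cfg, rng))
                         for _ in range(cfg.n_replicates)])
    rs_linear = np.array([_replicate_rs(*simulate_linear_scenario(cfg, rng))
                          for _ in range(cfg.n_replicates)])
    acc_ratio = float(np.mean(rs_ratio > cfg.rs_threshold))
    acc_linear = float(np.mean(rs_linear <= cfg.rs_threshold))
    overall = 0.5 * (acc_ratio + acc_linear)
    return ClassifierReport(acc_ratio, acc_linear, overall,
                            cfg.n_replicates, rs_ratio, rs_linear)
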