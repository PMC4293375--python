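"""The regression engine: marker-dosage vs trait simple OLS at scale.

Each (marker, trait) pair is fit by simple linear regression of the
trait on allele dosage — the allele frequency test.  With centered
sums over the n complete pairs

    Sxx = sum (x - xbar)^2,  Syy = sum (y - ybar)^2,  Sxy = sum (x - xbar)(y - ybar)

the fit is

    beta = Sxy / Sxx
    s^2  = (Syy - beta * Sxy) / (n - 2)
    se   = sqrt(s^2 / Sxx)
    t    = beta / se,  two-sided p from Student t on n - 2 df.

The scan streams markers once; for each marker the sufficient
statistics are accumulated per distinct trait-missingness mask, so a
block of fully-observed traits shares a single pass over the dosage
vector — the mechanism that makes testing many traits nearly free.

P-values come either from the exact Student-t tail or from a lookup
table of -log10 p on a |t| grid with linear interpolation, one cached
table per distinct df; |t| beyond the grid falls back to the exact
tail.  Extreme tails are computed in log space so p down to ~1e-300
is representable.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

import numpy as np
from scipy import stats

from .gen_io import AlleleStats, MarkerRecord, allele_stats
from .pheno import PhenotypeMatrix

__all__ = [
    "RegressionFit",
    "AssociationResult",
    "FilterSpec",
    "PValueTable",
    "PValueTableCache",
    "fit_simple_ols",
    "pvalue_exact",
    "neglog10_pvalue_exact",
    "build_pvalue_table",
    "pvalue_interpolated",
    "passes_filters",
    "batch_associate",
    "RESULT_COLUMNS",
    "write_results",
    "read_results",
]

#: minimum complete pairs for a testable regression (df = n - 2 >= 1)
MIN_COMPLETE_PAIRS = 3

#: default |t| grid extent and spacing for the lookup table
DEFAULT_T_MAX = 40.0
DEFAULT_T_STEP = 0.01

_LOG10 = math.log(10.0)


@dataclass
class RegressionFit:
    """One simple-OLS fit.  ``status`` is "ok", "degenerate" (perfect
    fit, se == 0, p undefined) or "untestable" (monomorphic dosage,
    constant trait residual handled as degenerate, or n_used < 3)."""

    beta: float
    se: float
    t_stat: float
    df: int
    p: float
    n_used: int
    status: str = "ok"

    @property
    def testable(self) -> bool:
        return self.status == "ok"


@dataclass
class AssociationResult:
    """One (marker, trait) association row."""

    snp_id: str
    rs_id: str
    position: int
    allele_a: str
    allele_b: str
    trait_name: str
    fit: RegressionFit
    allele_stats: AlleleStats


@dataclass
class FilterSpec:
    """Runtime thresholds; None (or the permissive default) disables a
    field.  A row passes iff mac >= mac_min, p <= p_max (inclusive),
    se <= se_max when set, and |beta| >= abs_beta_min."""

    mac_min: float = 0.0
    p_max: float = 1.0
    se_max: float | None = None
    abs_beta_min: float = 0.0

    def __post_init__(self) -> None:
        if self.mac_min < 0:
            raise ValueError("mac_min must be >= 0")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must be in (0, 1]")
        if self.se_max is not None and self.se_max <= 0:
            raise ValueError("se_max must be positive")
        if self.abs_beta_min < 0:
            raise ValueError("abs_beta_min must be >= 0")


# ---------------------------------------------------------------------------
# p-values: exact tail and lookup-table interpolation


def pvalue_exact(t_stat: float, df: int) -> float:
    """Two-sided Student-t p-value, 2*P(T_df >= |t|), safe in the tail."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    # survival function in log space keeps precision out to p ~ 1e-300
    logp = math.log(2.0) + stats.t.logsf(abs(t_stat), df)
    return min(1.0, math.exp(logp))


def neglog10_pvalue_exact(t_stat, df: int):
    """-log10 of the two-sided p, vectorised over t (table construction)."""
    logp = np.log(2.0) + stats.t.logsf(np.abs(t_stat), df)
    return np.minimum(0.0, logp) / -_LOG10


@dataclass
class PValueTable:
    """-log10 p sampled on an increasing |t| grid for one df."""

    df: int
    grid: np.ndarray
    neglog10p: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.neglog10p) < 0):
            raise ValueError("neglog10p must be nondecreasing along the grid")


def build_pvalue_table(df: int, t_max: float = DEFAULT_T_MAX,
                       step: float = DEFAULT_T_STEP) -> PValueTable:
    """Precompute -log10 p on the |t| grid [0, t_max] with the given step."""
    if step <= 0:
        raise ValueError("step must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    grid = np.arange(0.0, t_max + step / 2, step)
    return PValueTable(df, grid, neglog10_pvalue_exact(grid, df))


def pvalue_interpolated(t_stat: float, table: PValueTable) -> float:
    """Table p-value: linear interpolation on -log10 p between grid
    points; |t| beyond the table falls back to the exact tail."""
    at = abs(t_stat)
    if at > table.grid[-1]:
        return pvalue_exact(at, table.df)
    nlp = float(np.interp(at, table.grid, table.neglog10p))
    return 10.0 ** (-nlp)


class PValueTableCache:
    """Lazily builds and caches one PValueTable per distinct df."""

    def __init__(self, t_max: float = DEFAULT_T_MAX,
                 step: float = DEFAULT_T_STEP) -> None:
        self.t_max = t_max
        self.step = step
        self._tables: dict[int, PValueTable] = {}

    def __call__(self, t_stat: float, df: int) -> float:
        table = self._tables.get(df)
        if table is None:
            table = build_pvalue_table(df, self.t_max, self.step)
            self._tables[df] = table
        return pvalue_interpolated(t_stat, table)


def _pvalue_fn(mode: str) -> Callable[[float, int], float]:
    if mode == "exact":
        return pvalue_exact
    if mode in ("interp", "interpolated"):
        return PValueTableCache()
    raise ValueError(f"unknown pvalue mode {mode!r}")


# ---------------------------------------------------------------------------
# single-pair fit


def _fit_from_sums(n: int, sxx: float, syy: float, sxy: float,
                   pvalue: Callable[[float, int], float]) -> RegressionFit:
    """Assemble a RegressionFit from centered sums over complete pairs."""
    if n < MIN_COMPLETE_PAIRS:
        return RegressionFit(math.nan, math.nan, math.nan, max(n - 2, 0),
                             math.nan, n, status="untestable")
    if sxx <= 0:
        return RegressionFit(math.nan, math.nan, math.nan, n - 2,
                             math.nan, n, status="untestable")
    beta = sxy / sxx
    df = n - 2
    rss = syy - beta * sxy
    # guard tiny negative rounding residue
    s2 = max(rss, 0.0) / df
    if s2 == 0.0:
        # perfect fit (or constant trait with beta == 0): p undefined
        return RegressionFit(beta, 0.0, math.inf if beta else math.nan,
                             df, math.nan, n, status="degenerate")
    se = math.sqrt(s2 / sxx)
    t = beta / se
    return RegressionFit(beta, se, t, df, pvalue(t, df), n)


def fit_simple_ols(x: np.ndarray, y: np.ndarray,
                   pvalue_mode: str = "exact") -> RegressionFit:
    """Simple linear regression of y on x over the complete pairs.

    Missing entries (NaN) in either vector drop that individual.
    Monomorphic x or fewer than 3 complete pairs yields an
    "untestable" fit rather than an exception; a zero-residual fit is
    flagged "degenerate" (se = 0, p undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~np.isnan(x) & ~np.isnan(y)
    xc, yc = x[mask], y[mask]
    n = xc.size
    if n < MIN_COMPLETE_PAIRS:
        return _fit_from_sums(n, 0.0, 0.0, 0.0, pvalue_exact)
    xm, ym = xc.mean(), yc.mean()
    dx, dy = xc - xm, yc - ym
    return _fit_from_sums(n, float(dx @ dx), float(dy @ dy), float(dx @ dy),
                          _pvalue_fn(pvalue_mode))


# ---------------------------------------------------------------------------
# filters


def passes_filters(row: AssociationResult, filters: FilterSpec) -> bool:
    """Apply the runtime thresholds; untestable/degenerate rows never pass."""
    fit = row.fit
    if not fit.testable:
        return False
    if row.allele_stats.mac < filters.mac_min:
        return False
    if fit.p > filters.p_max:
        return False
    if filters.se_max is not None and fit.se > filters.se_max:
        return False
    if abs(fit.beta) < filters.abs_beta_min:
        return False
    return True


# ---------------------------------------------------------------------------
# the streaming scan


def _mask_groups(values: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group trait columns by identical missingness pattern.

    Returns (trait_indices, observed_row_mask) per group.  Traits
    sharing a mask share one pass over the dosage vector per marker.
    """
    observed = ~np.isnan(values)
    groups: dict[bytes, list[int]] = {}
    for j in range(values.shape[1]):
        groups.setdefault(observed[:, j].tobytes(), []).append(j)
    return [(np.array(cols), observed[:, cols[0]])
            for cols in groups.values()]


def batch_associate(
    markers: Iterable[MarkerRecord],
    pm: PhenotypeMatrix,
    filters: FilterSpec | None = None,
    pvalue_mode: str = "exact",
    untestable_sink: list | None = None,
) -> Iterator[AssociationResult]:
    """Test every marker against every trait in one streaming pass.

    Yields only rows passing ``filters``.  A marker failing the MAC
    threshold short-circuits before any trait is fit.  Untestable and
    degenerate pairs go to ``untestable_sink`` (as AssociationResult
    objects) when provided, never to the results stream.

    Raises if a marker's dosage length disagrees with the phenotype
    matrix — sample orders must already match (validated upstream
    against SAMPLE ids).
    """
    filters = filters or FilterSpec()
    pvalue = _pvalue_fn(pvalue_mode)
    groups = _mask_groups(pm.values)
    n_samples = pm.n_samples
    values = pm.values

    for marker in markers:
        if marker.dosages.shape[0] != n_samples:
            raise ValueError(
                f"marker {marker.snp_id}: {marker.dosages.shape[0]} genotypes "
                f"but {n_samples} phenotyped individuals")
        astats = allele_stats(marker.dosages)
        if not (astats.mac >= filters.mac_min):  # NaN mac fails too
            continue
        x_obs = ~np.isnan(marker.dosages)
        for cols, trait_mask in groups:
            mask = trait_mask & x_obs
            n = int(mask.sum())
            if n < MIN_COMPLETE_PAIRS:
                fits = [_fit_from_sums(n, 0.0, 0.0, 0.0, pvalue)] * len(cols)
            else:
                xs = marker.dosages[mask]
                ys = values[np.ix_(mask, cols)]
                dx = xs - xs.mean()
                sxx = float(dx @ dx)
                dy = ys - ys.mean(axis=0)
                sxy = dx @ dy
                syy = (dy * dy).sum(axis=0)
                fits = [_fit_from_sums(n, sxx, float(syy[k]), float(sxy[k]),
                                       pvalue)
                        for k in range(len(cols))]
            for j, fit in zip(cols, fits):
                row = AssociationResult(
                    marker.snp_id, marker.rs_id, marker.position,
                    marker.allele_a, marker.allele_b,
                    pm.trait_names[j], fit, astats)
                if not fit.testable:
                    if untestable_sink is not None:
                        untestable_sink.append(row)
                elif passes_filters(row, filters):
                    yield row
                # else: filtered out silently (counted by the caller's log)


# ---------------------------------------------------------------------------
# results file

RESULT_COLUMNS = ["snp_id", "rs_id", "pos", "allele_a", "allele_b", "trait",
                  "n", "eaf", "mac", "beta", "se", "t", "p"]


def write_results(rows: Iterable[AssociationResult], path,
                  *, gzip_out: bool = False) -> int:
    """Write association rows as a tab-delimited table; returns row count."""
    opener = gzip.open if gzip_out else open
    n = 0
    with opener(path, "wt") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            f, a = r.fit, r.allele_stats
            fh.write("\t".join([
                r.snp_id, r.rs_id, str(r.position), r.allele_a, r.allele_b,
                r.trait_name, str(f.n_used),
                "%.6g" % a.eaf, "%.6g" % a.mac,
                "%.10g" % f.beta, "%.10g" % f.se, "%.10g" % f.t_stat,
                "%.10g" % f.p,
            ]) + "\n")
            n += 1
    return n


def read_results(path):
    """Read a results file back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t",
                       dtype={"snp_id": str, "rs_id": str, "trait": str})
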