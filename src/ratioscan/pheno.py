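"""Trait-matrix construction, ratio (combinatorial) traits and transforms.

Ratio traits divide one measured trait by another; in metabolomics
GWAS such ratios can proxy enzymatic conversion rates and associate
more strongly than either component.  For n traits there are
n(n-1)/2 unordered pairs, each emitted once as numerator/denominator
with numerator before denominator in the input order (a flag enables
both directions).  The generated name "<num>_DIV_<den>" doubles as the
join key used later when reliability scores are attached.

Covariate adjustment (OLS residualisation) and the rank-based
inverse-normal transform are provided here so the whole adjustment
pipeline runs in one place before the scan.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .gen_io import GenFormatError, SampleTable

__all__ = [
    "PhenotypeMatrix",
    "RATIO_SEPARATOR",
    "generate_ratio_traits",
    "decode_ratio_name",
    "residualize",
    "inverse_normal_transform",
    "read_phenotype_table",
    "from_sample_table",
    "to_sample_table",
]

#: infix marking a generated ratio trait; also the RS-stage join key
RATIO_SEPARATOR = "_DIV_"


@dataclass
class PhenotypeMatrix:
    """Individuals x traits of continuous values with NaN missingness.

    ``provenance`` carries one tag per trait: "raw",
    ("ratio", numerator, denominator), or "transformed".
    """

    sample_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("trait names must be unique")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.trait_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} individuals x "
                f"{len(self.trait_names)} traits")
        if not self.provenance:
            self.provenance = ["raw"] * len(self.trait_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]


def from_sample_table(table: SampleTable,
                      traits: Sequence[str] | None = None) -> PhenotypeMatrix:
    """Extract the analyzable continuous traits from a SAMPLE table."""
    names = list(traits) if traits is not None else table.analyzable_traits()
    idx = [table.trait_names.index(n) for n in names]
    return PhenotypeMatrix(list(table.sample_ids), names,
                           table.values[:, idx].copy())


def to_sample_table(pm: PhenotypeMatrix) -> SampleTable:
    """Express a PhenotypeMatrix as a SAMPLE table (all traits type P)."""
    return SampleTable(list(pm.sample_ids), list(pm.trait_names),
                       ["P"] * pm.n_traits, pm.values.copy())


def read_phenotype_table(source, missing_tokens: Sequence[str] = ("NA",),
                         delimiter: str | None = None) -> PhenotypeMatrix:
    """Read a plain delimited phenotype table: header with an ID column
    first, then one row per individual.  Alternative to SAMPLE input."""
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            lines = [ln.split(delimiter) for ln in fh if ln.strip()]
    else:
        lines = [ln.split(delimiter) for ln in source if ln.strip()]
    if not lines:
        raise GenFormatError("empty phenotype table")
    header = [c.strip() for c in lines[0]]
    trait_names = header[1:]
    missing = set(missing_tokens)
    ids, rows = [], []
    for lineno, fields in enumerate(lines[1:], 2):
        fields = [c.strip() for c in fields]
        if len(fields) != len(header):
            raise GenFormatError(
                f"line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}")
        ids.append(fields[0])
        rows.append([float("nan") if c in missing else float(c)
                     for c in fields[1:]])
    return PhenotypeMatrix(ids, trait_names, np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# ratio traits


def generate_ratio_traits(
    pm: PhenotypeMatrix,
    traits: Sequence[str] | None = None,
    *,
    keep_original: bool = False,
    both_directions: bool = False,
    log_ratio: bool = False,
) -> PhenotypeMatrix:
    """Build all pairwise ratio traits from the selected traits.

    For n selected traits the output holds n(n-1)/2 ratios (each
    unordered pair once, earlier trait as numerator), or n(n-1) with
    ``both_directions``.  A ratio value is missing wherever its
    numerator or denominator is missing or the denominator is zero.
    ``log_ratio`` applies a natural log to the ratio (negative or zero
    ratios then become missing).  ``keep_original`` prepends the source
    traits to the output.
    """
    names = list(traits) if traits is not None else list(pm.trait_names)
    for n in names:
        if n not in pm.trait_names:
            raise KeyError(f"unknown trait {n!r}")
    if len(names) < 2 and not keep_original:
        # 0 or 1 traits -> no pairs; still a valid (empty) result
        pass
    existing = set(pm.trait_names)
    cols, out_names, prov = [], [], []
    if keep_original:
        for n in names:
            cols.append(pm.trait(n).copy())
            out_names.append(n)
            prov.append("raw")
    pairs = [(names[i], names[j])
             for i in range(len(names)) for j in range(i + 1, len(names))]
    if both_directions:
        pairs += [(b, a) for a, b in pairs]
    for num, den in pairs:
        name = f"{num}{RATIO_SEPARATOR}{den}"
        if name in existing or name in out_names:
            raise ValueError(
                f"generated ratio name {name!r} collides with an existing trait")
        x, y = pm.trait(num), pm.trait(den)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(y == 0, np.nan, x / y)
            if log_ratio:
                r = np.log(np.where(r > 0, r, np.nan))
        cols.append(r)
        out_names.append(name)
        prov.append(("ratio", num, den))
    values = (np.column_stack(cols) if cols
              else np.empty((pm.n_samples, 0)))
    return PhenotypeMatrix(list(pm.sample_ids), out_names, values, prov)


def decode_ratio_name(name: str) -> tuple[str, str]:
    """Split "<num>_DIV_<den>" back into (numerator, denominator)."""
    parts = name.split(RATIO_SEPARATOR)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(f"{name!r} is not a decodable ratio-trait name")
    return parts[0], parts[1]


# ---------------------------------------------------------------------------
# adjustment and transformation


def residualize(y: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of y on [intercept | covariates], complete cases only.

    Rows missing in y or any covariate remain NaN in the output.  With
    no covariates this is mean-centering.  Raises on a rank-deficient
    design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((y.shape[0], 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    mask = ~np.isnan(y) & ~np.isnan(covariates).any(axis=1)
    design = np.column_stack([np.ones(int(mask.sum())), covariates[mask]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which covariate columns fail to add rank
        bad = []
        base = design[:, :1]
        for j in range(covariates.shape[1]):
            cand = np.column_stack([base, design[:, j + 1]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(j)
            else:
                base = cand
        raise np.linalg.LinAlgError(
            f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
    out = np.full_like(y, np.nan)
    out[mask] = y[mask] - design @ coef
    return out


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Non-missing values are replaced by standard normal quantiles of
    (r - 3/8) / (m + 1/4) for average-tie rank r among the m non-missing
    values; missing entries stay missing.  Requires at least two
    distinct values (the transform is undefined for a constant trait).
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    vals = y[mask]
    if np.unique(vals).size < 2:
        raise ValueError("inverse-normal transform undefined for a "
                         "constant (or empty) trait")
    ranks = stats.rankdata(vals, method="average")
    quantiles = stats.norm.ppf((ranks - 3.0 / 8.0) / (vals.size + 0.25))
    out = np.full_like(y, np.nan)
    out[mask] = quantiles
    return out
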