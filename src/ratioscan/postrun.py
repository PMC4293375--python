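"""Post-run result mining: Reliability Scores, summaries, extraction.

The Reliability Score (RS) ranks a ratio-trait association against the
associations of its two component traits at the same marker:

    RS = min(p_numerator, p_denominator) / p_ratio

RS > 1 means the ratio associates more strongly (smaller p) than
either single trait — the analogue of the "p-gain" used in
metabolomics GWAS.  The arithmetic is done in log10 space so that
p-values near the double underflow boundary survive.

Also here: per-marker best-trait summaries and the generic
count/extract utility for slicing a results table with composed
filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assoc import FilterSpec
from .pheno import decode_ratio_name

__all__ = [
    "RSRecord",
    "SummaryRow",
    "reliability_score",
    "log10_reliability_score",
    "annotate_rs",
    "filter_rs",
    "best_trait_summary",
    "count_and_extract",
    "write_rs_records",
    "write_summary",
]

_MARKER_COLS = ["snp_id", "rs_id", "pos", "allele_a", "allele_b"]


@dataclass
class RSRecord:
    """A ratio-trait association joined to its single-trait p-values."""

    snp_id: str
    rs_id: str
    position: int
    allele_a: str
    allele_b: str
    ratio_trait: str
    numerator_trait: str
    denominator_trait: str
    p_comb: float
    p_num: float
    p_den: float
    rs: float

    @property
    def p_smaller_single(self) -> float:
        return min(self.p_num, self.p_den)

    @property
    def log10_rs(self) -> float:
        return log10_reliability_score(self.p_num, self.p_den, self.p_comb)


@dataclass
class SummaryRow:
    """Per-marker strongest-associating trait under a chosen criterion."""

    snp_id: str
    rs_id: str
    position: int
    allele_a: str
    allele_b: str
    best_trait: str
    criterion: str
    criterion_value: float


def _check_p(name: str, p: float) -> None:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"{name} must be in (0, 1], got {p}")


def log10_reliability_score(p_num: float, p_den: float, p_comb: float) -> float:
    """log10 RS = log10 min(p_num, p_den) - log10 p_comb."""
    _check_p("p_num", p_num)
    _check_p("p_den", p_den)
    _check_p("p_comb", p_comb)
    return math.log10(min(p_num, p_den)) - math.log10(p_comb)


def reliability_score(p_num: float, p_den: float, p_comb: float) -> float:
    """RS = min(p_num, p_den) / p_comb, computed via log10 to survive
    extreme tails.  Symmetric in the two single-trait p-values."""
    return 10.0 ** log10_reliability_score(p_num, p_den, p_comb)


# ---------------------------------------------------------------------------
# joining scan output


def annotate_rs(
    comb_results: pd.DataFrame,
    single_results: pd.DataFrame,
) -> tuple[list[RSRecord], list[tuple[str, str, str]]]:
    """Join ratio-trait rows to their component single-trait rows.

    ``comb_results`` holds scan rows whose trait names encode a ratio
    ("<num>_DIV_<den>"); ``single_results`` holds raw-trait rows.  Both
    use the scan's output columns.  Returns the RS records plus an
    unmatched list of (snp_id, ratio_trait, missing_single) for markers
    whose single-trait row was filtered out upstream — reported, never
    silently dropped.
    """
    singles = {(r.snp_id, r.trait): r.p
               for r in single_results.itertuples(index=False)}
    records: list[RSRecord] = []
    unmatched: list[tuple[str, str, str]] = []
    for row in comb_results.itertuples(index=False):
        num, den = decode_ratio_name(row.trait)
        p_num = singles.get((row.snp_id, num))
        p_den = singles.get((row.snp_id, den))
        if p_num is None or p_den is None:
            missing = num if p_num is None else den
            unmatched.append((row.snp_id, row.trait, missing))
            continue
        records.append(RSRecord(
            row.snp_id, row.rs_id, int(row.pos), row.allele_a, row.allele_b,
            row.trait, num, den,
            p_comb=float(row.p), p_num=float(p_num), p_den=float(p_den),
            rs=reliability_score(p_num, p_den, row.p)))
    return records, unmatched


def filter_rs(rows: Iterable[RSRecord], rs_min: float) -> list[RSRecord]:
    """Keep records with RS >= rs_min (rs_min must be positive)."""
    if rs_min <= 0:
        raise ValueError("rs_min must be > 0")
    return [r for r in rows if r.rs >= rs_min]


def write_rs_records(records: Sequence[RSRecord], path) -> None:
    cols = _MARKER_COLS + ["ratio_trait", "numerator", "denominator",
                           "p_num", "p_den", "p_comb", "rs", "log10_rs"]
    with open(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.snp_id, r.rs_id, str(r.position), r.allele_a, r.allele_b,
                r.ratio_trait, r.numerator_trait, r.denominator_trait,
                "%.10g" % r.p_num, "%.10g" % r.p_den, "%.10g" % r.p_comb,
                "%.10g" % r.rs, "%.10g" % r.log10_rs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# summaries and extraction


def best_trait_summary(results: pd.DataFrame,
                       criterion: str = "min-p") -> list[SummaryRow]:
    """Strongest-associating trait per marker.

    ``criterion`` is "min-p" (smallest p-value) or "max-|beta|"
    (largest absolute effect).  Ties break to the lexicographically
    first trait name, deterministically.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    if criterion == "min-p":
        key = results["p"].to_numpy()
        better = np.less
    elif criterion == "max-|beta|":
        key = np.abs(results["beta"].to_numpy())
        better = np.greater
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    best: dict[str, tuple[float, str, tuple]] = {}
    for i, row in enumerate(results.itertuples(index=False)):
        cur = best.get(row.snp_id)
        if (cur is None or better(key[i], cur[0])
                or (key[i] == cur[0] and row.trait < cur[1])):
            best[row.snp_id] = (key[i], row.trait, row)
    out = []
    for snp_id, (val, trait, row) in best.items():
        out.append(SummaryRow(row.snp_id, row.rs_id, int(row.pos),
                              row.allele_a, row.allele_b, trait,
                              criterion, float(val)))
    return out


def write_summary(rows: Sequence[SummaryRow], path) -> None:
    cols = _MARKER_COLS + ["best_trait", "criterion", "criterion_value"]
    with open(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.snp_id, r.rs_id, str(r.position), r.allele_a, r.allele_b,
                r.best_trait, r.criterion, "%.10g" % r.criterion_value,
            ]) + "\n")


def count_and_extract(
    results: pd.DataFrame,
    filters: FilterSpec | None = None,
    rs_min: float | None = None,
    group_by: str = "marker",
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter a results table and count survivors per group.

    Filters compose conjunctively: the FilterSpec thresholds (applied
    to the mac/p/se/beta columns present in the table) and, for RS
    tables, ``rs_min`` on the rs column.  ``group_by`` is "marker"
    (snp_id) or "trait".  Returns (surviving rows, per-group counts).
    """
    df = results
    if filters is not None:
        mask = np.ones(len(df), dtype=bool)
        if "mac" in df:
            mask &= df["mac"].to_numpy() >= filters.mac_min
        mask &= df["p"].to_numpy() <= filters.p_max
        if filters.se_max is not None and "se" in df:
            mask &= df["se"].to_numpy() <= filters.se_max
        if "beta" in df:
            mask &= np.abs(df["beta"].to_numpy()) >= filters.abs_beta_min
        df = df[mask]
    if rs_min is not None:
        if rs_min <= 0:
            raise ValueError("rs_min must be > 0")
        if "rs" not in df:
            raise KeyError("results table has no rs column")
        df = df[df["rs"].to_numpy() >= rs_min]
    if group_by == "marker":
        key = "snp_id"
    elif group_by == "trait":
        key = "ratio_trait" if "ratio_trait" in df else "trait"
    else:
        raise KeyError(f"unknown group key {group_by!r}")
    counts = df.groupby(key, sort=True).size()
    return df.reset_index(drop=True), counts
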