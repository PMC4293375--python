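"""Streaming I/O for Oxford GEN/SAMPLE genotype and phenotype files.

A GEN file holds one genetic marker per line: five metadata columns
(snp id, rs id, position, allele A, allele B) — optionally preceded by a
chromosome column — followed by three genotype probabilities
(AA, AB, BB) per individual.  The probabilities are collapsed to an
*allele dosage*, the expected count of allele B:

    dosage = p_AB + 2 * p_BB

Allele B is therefore the effect allele throughout the package.
Probabilities are not renormalised; a triple whose sum falls below a
completeness threshold (default 0.1) is treated as a missing genotype.

The companion SAMPLE file carries the phenotypes: a header row
(ID_1 ID_2 missing <trait names...>), a type-code row (0 for the ID
columns, then P/C for continuous traits, D for discrete covariates,
B for binary traits), and one data row per individual.

Files are read in fixed-size chunks so that arbitrarily large inputs
stream with bounded memory; gzip input is decompressed transparently.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterator, Sequence

import numpy as np

__all__ = [
    "MarkerRecord",
    "SampleTable",
    "AlleleStats",
    "GenFormatError",
    "DEFAULT_COMPLETENESS_THRESHOLD",
    "DEFAULT_CHUNK_BYTES",
    "dosage_from_probs",
    "parse_gen_stream",
    "parse_gen_file",
    "read_sample_file",
    "write_sample_file",
    "write_gen_file",
    "allele_stats",
]

#: genotype triples summing below this are treated as missing calls
DEFAULT_COMPLETENESS_THRESHOLD = 0.1

#: default read-buffer size for chunked streaming
DEFAULT_CHUNK_BYTES = 1 << 20

#: missing-value sentinel used in written files
MISSING_TOKEN = "NA"

#: SAMPLE type codes regarded as continuous, analyzable traits
_CONTINUOUS_CODES = {"P", "C"}
_KNOWN_CODES = {"0", "P", "C", "D", "B"}


class GenFormatError(ValueError):
    """Malformed GEN or SAMPLE content (wrong field counts, bad numbers...)."""


@dataclass
class MarkerRecord:
    """One marker's metadata plus per-individual allele dosages.

    ``dosages`` is a float array with NaN marking missing genotypes;
    every non-missing entry lies in [0, 2].
    """

    snp_id: str
    rs_id: str
    position: int
    allele_a: str
    allele_b: str
    dosages: np.ndarray
    chrom: str | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]


@dataclass
class AlleleStats:
    """Per-marker allele summaries on fractional dosages (no rounding).

    ``mac`` is min(S, 2*n_typed - S) for dosage sum S over typed
    individuals; ``eaf`` = S / (2*n_typed).  With no typed individuals
    both are NaN and ``n_typed`` is 0.
    """

    mac: float
    eaf: float
    n_typed: int


@dataclass
class SampleTable:
    """Phenotype table read from a SAMPLE file.

    ``values`` is individuals x traits with NaN for missing entries.
    ``trait_types`` holds the raw type codes; continuous traits (codes
    P or C) are the analyzable ones, D columns are covariates.
    """

    sample_ids: list[str]
    trait_names: list[str]
    trait_types: list[str]
    values: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def analyzable_traits(self) -> list[str]:
        """Names of continuous traits exposed for association testing."""
        return [n for n, t in zip(self.trait_names, self.trait_types)
                if t in _CONTINUOUS_CODES]

    def covariate_traits(self) -> list[str]:
        return [n for n, t in zip(self.trait_names, self.trait_types)
                if t == "D"]

    def trait_values(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]


# ---------------------------------------------------------------------------
# dosage conversion


def dosage_from_probs(
    triple: Sequence[float],
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
    marker: str = "<unknown>",
) -> float:
    """Collapse one (p_AA, p_AB, p_BB) triple to an allele-B dosage.

    Returns NaN when the probabilities sum below the completeness
    threshold (an effectively uncalled genotype).  Probabilities are
    used as given — no renormalisation.
    """
    if len(triple) != 3:
        raise GenFormatError(
            f"marker {marker}: genotype triple has {len(triple)} components")
    p_aa, p_ab, p_bb = (float(v) for v in triple)
    if p_aa < 0 or p_ab < 0 or p_bb < 0:
        raise GenFormatError(f"marker {marker}: negative genotype probability")
    if p_aa + p_ab + p_bb < completeness_threshold:
        return float("nan")
    return p_ab + 2.0 * p_bb


def _triples_to_dosages(
    probs: np.ndarray, completeness_threshold: float, marker: str
) -> np.ndarray:
    """Vectorised dosage conversion for a (n, 3) probability array."""
    if np.any(probs < 0):
        raise GenFormatError(f"marker {marker}: negative genotype probability")
    dosages = probs[:, 1] + 2.0 * probs[:, 2]
    dosages[probs.sum(axis=1) < completeness_threshold] = np.nan
    return dosages


# ---------------------------------------------------------------------------
# GEN streaming


def _open_maybe_gzip(source) -> tuple[IO[bytes], list[IO[bytes]]]:
    """Open a path or stream for reading, decompressing gzip transparently.

    Returns the stream to read plus the list of handles to close when
    done (empty when the caller owns the stream).
    """
    owned: list[IO[bytes]] = []
    if isinstance(source, (str, os.PathLike)):
        raw = open(source, "rb")
        owned.append(raw)
    else:
        raw = source
    # sniff the gzip magic rather than trusting the file name
    head = raw.read(2)
    if raw.seekable():
        raw.seek(-len(head), io.SEEK_CUR)
    else:  # pragma: no cover - non-seekable input
        raw = io.BytesIO(head + raw.read())
    if head == b"\x1f\x8b":
        gz = gzip.GzipFile(fileobj=raw, mode="rb")
        owned.insert(0, gz)
        return gz, owned
    return raw, owned


def _iter_chunk_lines(stream: IO[bytes], chunk_bytes: int) -> Iterator[bytes]:
    """Yield complete lines from a byte stream read in fixed-size chunks."""
    tail = b""
    while True:
        chunk = stream.read(chunk_bytes)
        if not chunk:
            break
        tail += chunk
        lines = tail.split(b"\n")
        tail = lines.pop()
        for line in lines:
            if line.endswith(b"\r"):
                line = line[:-1]
            if line.strip():
                yield line
    if tail.strip():
        yield tail.rstrip(b"\r")


def parse_gen_stream(
    source,
    n_samples: int,
    *,
    chrom_column: bool = False,
    chunk_bytes: int = DEFAULT_CHUNK_BYTES,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
) -> Iterator[MarkerRecord]:
    """Stream MarkerRecords from a GEN file (path or binary stream).

    Parameters
    ----------
    source
        Path or binary file object; gzip content is detected by magic
        bytes and decompressed on the fly.
    n_samples
        Number of individuals declared by the companion SAMPLE file;
        each line must carry exactly ``3 * n_samples`` probabilities.
    chrom_column
        If True, lines begin with a chromosome column before the five
        standard metadata fields.
    chunk_bytes
        Read-buffer size.  The record sequence is independent of it.
    """
    if chunk_bytes < 1:
        raise ValueError("chunk_bytes must be positive")
    n_meta = 6 if chrom_column else 5
    expected = n_meta + 3 * n_samples
    stream, owned = _open_maybe_gzip(source)
    try:
        for lineno, line in enumerate(_iter_chunk_lines(stream, chunk_bytes), 1):
            fields = line.split()
            if len(fields) != expected:
                raise GenFormatError(
                    f"line {lineno}: expected {expected} fields "
                    f"({n_meta} metadata + 3x{n_samples} probabilities), "
                    f"got {len(fields)}")
            meta = [f.decode() for f in fields[:n_meta]]
            chrom = meta.pop(0) if chrom_column else None
            snp_id, rs_id, pos_s, allele_a, allele_b = meta
            try:
                position = int(pos_s)
                probs = np.array(fields[n_meta:], dtype=float)
            except ValueError as exc:
                raise GenFormatError(
                    f"marker {snp_id}: unparseable number ({exc})") from None
            probs = probs.reshape(n_samples, 3)
            dosages = _triples_to_dosages(probs, completeness_threshold, snp_id)
            yield MarkerRecord(snp_id, rs_id, position, allele_a, allele_b,
                               dosages, chrom=chrom)
    finally:
        for fh in owned:
            fh.close()


def parse_gen_file(path, n_samples: int, **kwargs) -> list[MarkerRecord]:
    """Eagerly parse a whole GEN file (convenience for small inputs)."""
    return list(parse_gen_stream(path, n_samples, **kwargs))


def write_gen_file(path, markers: Sequence[MarkerRecord],
                   *, gzip_out: bool = False, precision: int = 6) -> None:
    """Write markers as GEN lines of hard probability triples.

    A dosage d is decomposed as the expectation-preserving pair of
    adjacent hard calls (e.g. d=1.3 -> 0.7*AB + 0.3*BB); NaN dosages
    become the all-zero triple, which parses back as missing.
    """
    opener = gzip.open if gzip_out else open
    fmt = f"%.{precision}g"
    with opener(path, "wt") as fh:
        for m in markers:
            parts = [m.snp_id, m.rs_id, str(m.position), m.allele_a, m.allele_b]
            for d in m.dosages:
                if np.isnan(d):
                    parts += ["0", "0", "0"]
                else:
                    p_bb = max(d - 1.0, 0.0)
                    p_ab = d - 2.0 * p_bb
                    p_aa = 1.0 - p_ab - p_bb
                    parts += [fmt % p_aa, fmt % p_ab, fmt % p_bb]
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# SAMPLE files


def read_sample_file(
    source,
    missing_tokens: Sequence[str] = (MISSING_TOKEN,),
) -> SampleTable:
    """Read an Oxford SAMPLE phenotype file.

    Expects the standard two header rows: column names, then type
    codes.  ``missing_tokens`` lists the strings mapped to NaN
    (add "-9" for cohorts using that convention).
    """
    if isinstance(source, (str, os.PathLike)):
        fh = open(source, "rt")
        close = True
    else:
        fh = source
        close = False
    try:
        lines = [ln.split() for ln in fh if ln.strip()]
    finally:
        if close:
            fh.close()
    if len(lines) < 2:
        raise GenFormatError("SAMPLE file needs a header row and a type row")
    header, types = lines[0], lines[1]
    if len(header) != len(types):
        raise GenFormatError(
            f"header has {len(header)} columns but type row has {len(types)}")
    if len(header) < 3:
        raise GenFormatError("SAMPLE header must start with ID_1 ID_2 missing")
    trait_names = header[3:]
    trait_types = types[3:]
    for name, code in zip(trait_names, trait_types):
        if code not in _KNOWN_CODES:
            raise GenFormatError(f"column {name}: unknown type code {code!r}")
    missing = set(missing_tokens)
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, fields in enumerate(lines[2:], 3):
        if len(fields) != len(header):
            raise GenFormatError(
                f"line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}")
        sample_ids.append(fields[0])
        row = []
        for name, cell in zip(trait_names, fields[3:]):
            if cell in missing:
                row.append(float("nan"))
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise GenFormatError(
                        f"line {lineno}, column {name}: "
                        f"unparseable value {cell!r}") from None
        rows.append(row)
    values = (np.array(rows, dtype=float)
              if rows else np.empty((0, len(trait_names))))
    return SampleTable(sample_ids, trait_names, trait_types, values)


def write_sample_file(path, table: SampleTable, *, precision: int = 10) -> None:
    """Write a SampleTable in SAMPLE format (NA for missing)."""
    fmt = f"%.{precision}g"
    with open(path, "wt") as fh:
        fh.write(" ".join(["ID_1", "ID_2", "missing"] + table.trait_names) + "\n")
        fh.write(" ".join(["0", "0", "0"] + table.trait_types) + "\n")
        for i, sid in enumerate(table.sample_ids):
            cells = [MISSING_TOKEN if np.isnan(v) else fmt % v
                     for v in table.values[i]]
            fh.write(" ".join([sid, sid, "0"] + cells) + "\n")


# ---------------------------------------------------------------------------
# allele statistics


def allele_stats(dosages: np.ndarray) -> AlleleStats:
    """Minor allele count, effect-allele frequency and typed count.

    MAC is computed on fractional dosages — dosages are expectations
    and rounding would silently change filter behaviour.
    """
    d = np.asarray(dosages, dtype=float)
    typed = ~np.isnan(d)
    n_typed = int(typed.sum())
    if n_typed == 0:
        return AlleleStats(mac=float("nan"), eaf=float("nan"), n_typed=0)
    s = float(d[typed].sum())
    mac = min(s, 2.0 * n_typed - s)
    eaf = s / (2.0 * n_typed)
    return AlleleStats(mac=mac, eaf=eaf, n_typed=n_typed)
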