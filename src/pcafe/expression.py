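"""Expression-matrix ingestion, validation, and per-sample normalization.

The pipeline consumes a probe-by-sample signal matrix exported to
tab-separated text (probes as rows, samples as columns), a sample metadata
table assigning each sample to one of exactly two groups (e.g. control /
case), and an optional probe-to-gene-symbol mapping table in which a single
probe may map to several symbols.

All downstream stages assume the matrix has been column z-normalized
(each sample column has mean 0 and unit sample standard deviation), so
``normalize_samples`` is the canonical entry point after ``read_expression``.
Missing or non-numeric cells are hard errors: no imputation is performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleGroups",
    "ProbeGeneMap",
    "ExpressionFormatError",
    "NormalizationError",
    "read_expression",
    "write_expression",
    "read_groups",
    "read_probe_map",
    "normalize_samples",
    "map_probes",
]


class ExpressionFormatError(ValueError):
    """Raised when an input table violates the expression-matrix contract."""


class NormalizationError(ValueError):
    """Raised when a sample column cannot be z-scored (zero variance)."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen: set = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise ExpressionFormatError(f"duplicate {what} id(s): {sorted(set(map(str, dups)))}")


@dataclass
class ExpressionMatrix:
    """A validated probe-by-sample real matrix.

    ``data`` holds expression values x_ij (probe i, sample j) indexed by
    probe id with sample ids as columns.  Values are in arbitrary signal
    units before normalization and z-units after.  Construction validates
    the container invariants: unique ids, fully numeric, no missing cells.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "probe")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ExpressionFormatError("expression values must be numeric")
        if values.size and not np.isfinite(values.astype(float)).all():
            i, j = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise ExpressionFormatError(
                f"missing/non-finite value at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_probes(self, probe_ids: Iterable) -> "ExpressionMatrix":
        """Row-restrict to ``probe_ids`` (order preserved as given)."""
        ids = list(probe_ids)
        missing = [p for p in ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[ids], meta=dict(self.meta))


@dataclass
class SampleGroups:
    """Assignment of every sample to one of exactly two group labels."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        self.assignments = dict(self.assignments)
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValueError(f"exactly two group labels required, got {labels}")

    @property
    def labels(self) -> tuple:
        """The two group labels, lexicographically sorted."""
        return tuple(sorted(set(self.assignments.values())))

    def members(self, label: str) -> list:
        return [s for s, g in self.assignments.items() if g == label]

    def check_covers(self, sample_ids: Iterable) -> None:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")


@dataclass
class ProbeGeneMap:
    """Probe-to-gene-symbol mapping; one probe may map to several symbols."""

    entries: list  # of (probe_id, gene_symbol)

    def __post_init__(self) -> None:
        self.entries = [(str(p), str(g)) for p, g in self.entries]
        _check_unique(self.entries, "probe/gene pair")

    def symbols_for(self, probe_id: str) -> list:
        return [g for p, g in self.entries if p == probe_id]


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, col 1 = probe ids).

    Raises :class:`ExpressionFormatError` on duplicate ids and on any
    missing or non-numeric cell, naming the offending probe and sample.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise ExpressionFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    raw = pd.read_csv(
        io.StringIO(text), sep="\t", skiprows=1, header=None, index_col=0, dtype=str
    )
    if raw.shape[1] != len(sample_ids):
        raise ExpressionFormatError(
            f"{path}: header has {len(sample_ids)} samples but rows have {raw.shape[1]} values"
        )
    raw.columns = sample_ids
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "probe")
    bad = raw.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = raw.iat[i, j]
        raise ExpressionFormatError(
            f"{path}: non-numeric or missing cell {cell!r} at probe "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    # numpy's parser is correctly rounded, so full-precision text round-trips
    values = raw.to_numpy(dtype=str).astype(np.float64)
    return ExpressionMatrix(pd.DataFrame(values, index=raw.index, columns=raw.columns))


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write a matrix to TSV at full float precision (round-trip safe)."""
    df = m.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=None)


def read_groups(path) -> SampleGroups:
    """Read sample metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ExpressionFormatError(f"{path}: missing column {col!r}")
    _check_unique(list(df["sample_id"]), "sample")
    return SampleGroups(dict(zip(df["sample_id"], df["group"])))


def read_probe_map(path) -> ProbeGeneMap:
    """Read a probe map TSV with columns ``probe_id`` and ``gene_symbol``.

    Repeated probe_id rows are allowed (one probe, many symbols); exact
    duplicate pairs are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise ExpressionFormatError(f"{path}: missing column {col!r}")
    return ProbeGeneMap(list(zip(df["probe_id"], df["gene_symbol"])))


def normalize_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Column z-normalization: each sample to mean 0, sd 1 (n-1 denominator).

    This mirrors applying ``scale`` per sample column.  A column with zero
    variance cannot be normalized and raises :class:`NormalizationError`
    naming the sample.
    """
    values = m.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise NormalizationError(
            f"zero-variance sample column(s): {[m.sample_ids[j] for j in degenerate]}"
        )
    out = (values - mean) / sd
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        meta=dict(m.meta, normalized=True),
    )


def map_probes(probes: Iterable, pmap: ProbeGeneMap) -> tuple[list, list]:
    """Map probe ids to the de-duplicated union of gene symbols.

    Returns ``(symbols, unmapped)``: symbols in first-appearance order
    (a probe mapping to several symbols contributes all of them), and the
    list of probes with no entry in the map (reported, never silently
    dropped).
    """
    lookup: dict = {}
    for p, g in pmap.entries:
        lookup.setdefault(p, []).append(g)
    symbols: list = []
    seen: set = set()
    unmapped: list = []
    for probe in probes:
        probe = str(probe)
        if probe not in lookup:
            unmapped.append(probe)
            continue
        for g in lookup[probe]:
            if g not in seen:
                seen.add(g)
                symbols.append(g)
    return symbols, unmapped
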