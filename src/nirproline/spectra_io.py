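"""CSV input/output for spectra and reference concentration tables.

Dialect (RFC 4180, UTF-8, "." decimal):

* Spectra: first column ``sample_id``, remaining column headers are
  wavenumbers in cm^-1; one row per sample; rows = samples. Descending
  wavenumbers are canonical; ascending input is accepted and reversed with
  a logged notice.
* Reference: two columns ``sample_id, concentration`` (mg/ml); the header
  line is optional on read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import WavenumberGrid

__all__ = [
    "SpectrumSet",
    "ReferenceTable",
    "SpectraIOError",
    "RaggedRowError",
    "NonNumericCellError",
    "DuplicateSampleIdError",
    "SampleJoinError",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "join_reference",
]

logger = logging.getLogger(__name__)


class SpectraIOError(ValueError):
    """Base class for table-format violations."""


class RaggedRowError(SpectraIOError):
    """A data row has a different number of fields than the header."""


class NonNumericCellError(SpectraIOError):
    """A cell expected to be numeric failed to parse."""


class DuplicateSampleIdError(SpectraIOError):
    """The same sample identifier appears more than once."""


class SampleJoinError(KeyError):
    """A sample id present in one table is missing from the other."""


@dataclass
class SpectrumSet:
    """Absorbance spectra of a sample cohort on a shared wavenumber grid."""

    sample_ids: list[str]
    grid: WavenumberGrid
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix (samples x variables)")
        if a.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match number of sample ids")
        if a.shape[1] != len(self.grid):
            raise ValueError("column count does not match grid length")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateSampleIdError("sample ids are not unique")
        self.absorbance = a

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.grid)

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectrumSet":
        """Same cohort and grid, new absorbance matrix."""
        return SpectrumSet(list(self.sample_ids), self.grid, absorbance)

    def subset(self, ids: list[str]) -> "SpectrumSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise SampleJoinError(f"sample id(s) not in spectrum set: {missing}")
        rows = [index[s] for s in ids]
        return SpectrumSet(list(ids), self.grid, self.absorbance[rows])


@dataclass
class ReferenceTable:
    """Per-sample analyte concentration (mg/ml) from the reference method."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for sid, c in self.concentrations.items():
            c = float(c)
            if not np.isfinite(c) or c <= 0:
                raise SpectraIOError(
                    f"reference concentration for {sid!r} must be finite and > 0, got {c}"
                )
            self.concentrations[sid] = c

    def __len__(self) -> int:
        return len(self.concentrations)

    def __getitem__(self, sample_id: str) -> float:
        return self.concentrations[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.concentrations


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise NonNumericCellError(f"non-numeric value {text!r} in {where}") from exc


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a spectra CSV into a validated :class:`SpectrumSet`."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraIOError(f"{path} is empty") from None
        if len(header) < 2:
            raise SpectraIOError(f"{path}: header must hold sample_id plus wavenumbers")
        wavenumbers = [_parse_float(h, f"{path} header") for h in header[1:]]
        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise RaggedRowError(
                    f"{path} line {lineno}: {len(row)} fields, expected {len(header)}"
                )
            sid = row[0]
            if sid in seen:
                raise DuplicateSampleIdError(f"{path}: duplicate sample id {sid!r}")
            seen.add(sid)
            ids.append(sid)
            rows.append([_parse_float(v, f"{path} line {lineno}") for v in row[1:]])
    absorbance = np.asarray(rows, dtype=float).reshape(len(ids), len(wavenumbers))
    grid = WavenumberGrid(np.asarray(wavenumbers))
    if not grid.is_descending:
        logger.info("%s: ascending wavenumber grid reversed to canonical descending order", path)
        grid = grid.reversed()
        absorbance = absorbance[:, ::-1]
    return SpectrumSet(ids, grid, absorbance)


def write_spectra(s: SpectrumSet, path: str | Path) -> None:
    """Write a :class:`SpectrumSet` at full float precision."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id"] + [format(v, ".17g") for v in s.grid.values])
        for sid, row in zip(s.sample_ids, s.absorbance):
            writer.writerow([sid] + [format(v, ".17g") for v in row])


def read_reference(path: str | Path) -> ReferenceTable:
    """Read a two-column (sample_id, concentration) CSV; header optional."""
    path = Path(path)
    concs: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != 2:
                raise RaggedRowError(f"{path} line {lineno}: expected 2 fields, got {len(row)}")
            sid, raw = row
            if lineno == 1 and sid == "sample_id":
                continue  # header line
            value = _parse_float(raw, f"{path} line {lineno}")
            if sid in concs:
                raise DuplicateSampleIdError(f"{path}: duplicate sample id {sid!r}")
            concs[sid] = value
    return ReferenceTable(concs)


def write_reference(ref: ReferenceTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "concentration"])
        for sid, c in ref.concentrations.items():
            writer.writerow([sid, format(c, ".17g")])


def join_reference(s: SpectrumSet, ref: ReferenceTable) -> np.ndarray:
    """Concentration vector aligned with ``s.sample_ids``.

    Raises :class:`SampleJoinError` naming the first sample id without a
    reference value.
    """
    missing = [sid for sid in s.sample_ids if sid not in ref]
    if missing:
        raise SampleJoinError(f"no reference concentration for sample id(s): {missing}")
    return np.asarray([ref[sid] for sid in s.sample_ids], dtype=float)
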