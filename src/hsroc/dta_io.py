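"""Reading and validation of per-study 2x2 diagnostic count tables.

Input files are delimiter-separated text (comma, semicolon, tab or space)
with a header row and exactly five columns: ``study_name``, ``TP``, ``FN``,
``FP``, ``TN``.  Header names are matched case-insensitively and may appear
in any order; extra columns are rejected rather than ignored so that a
silently shifted column cannot masquerade as data.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "StudyRecord",
    "DTADataset",
    "DsvFormatError",
    "DatasetValidationError",
    "DELIMITERS",
    "read_dsv",
    "write_dsv",
    "validate_dataset",
    "example_dataset",
]

#: Supported delimiter names -> pandas ``sep`` argument.  A run of spaces is
#: one separator, so space-delimited files must not contain spaces inside
#: study names.
DELIMITERS = {
    "comma": ",",
    "semicolon": ";",
    "tab": "\t",
    "space": r"\s+",
}

_REQUIRED = ("study_name", "tp", "fn", "fp", "tn")
_COUNT_FIELDS = ("tp", "fn", "fp", "tn")


class DsvFormatError(ValueError):
    """File structure error: missing/duplicated columns or empty body."""


class DatasetValidationError(ValueError):
    """Dataset-level invariant violation (too few studies, duplicate IDs)."""


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 table: TP/FN among diseased, FP/TN among non-diseased."""

    study_name: str
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"count {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"count {name!r} must be >= 0, got {v}")
        if self.tp + self.fn < 1:
            raise ValueError(
                f"study {self.study_name!r}: needs at least one diseased subject (TP+FN >= 1)"
            )
        if self.fp + self.tn < 1:
            raise ValueError(
                f"study {self.study_name!r}: needs at least one non-diseased subject (FP+TN >= 1)"
            )

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn


@dataclass
class DTADataset:
    """Ordered collection of :class:`StudyRecord`."""

    studies: list[StudyRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterable[StudyRecord]:
        return iter(self.studies)

    def __getitem__(self, i: int) -> StudyRecord:
        return self.studies[i]

    def counts(self) -> pd.DataFrame:
        """The dataset as a DataFrame with columns study_name, TP, FN, FP, TN."""
        return pd.DataFrame(
            {
                "study_name": [s.study_name for s in self.studies],
                "TP": [s.tp for s in self.studies],
                "FN": [s.fn for s in self.studies],
                "FP": [s.fp for s in self.studies],
                "TN": [s.tn for s in self.studies],
            }
        )


def _coerce_count(value, row: int, name: str) -> int:
    """Accept integers and integral floats/strings ('90' or '90.0'); reject '90.5'."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row}: field {name!r} is not a number: {value!r}"
        ) from None
    if math.isnan(f) or f != int(f):
        raise ValueError(f"row {row}: field {name!r} must be an integer, got {value!r}")
    if f < 0:
        raise ValueError(f"row {row}: field {name!r} must be >= 0, got {value!r}")
    return int(f)


def read_dsv(source: Union[str, os.PathLike, io.TextIOBase], delimiter: str = "comma") -> DTADataset:
    """Read a delimiter-separated study table.

    Parameters
    ----------
    source
        A path to the file, an open text stream, or a string containing the
        file's text (a multi-line string is treated as content, not a path).
    delimiter
        One of ``comma``, ``semicolon``, ``tab``, ``space``.

    Returns
    -------
    DTADataset with records in file order.
    """
    if delimiter not in DELIMITERS:
        raise ValueError(
            f"delimiter must be one of {sorted(DELIMITERS)}, got {delimiter!r}"
        )
    sep = DELIMITERS[delimiter]

    if isinstance(source, str) and ("\n" in source or not os.path.exists(source)):
        handle: Union[io.StringIO, str, os.PathLike] = io.StringIO(source)
    else:
        handle = source

    engine = "python" if delimiter == "space" else "c"
    try:
        frame = pd.read_csv(handle, sep=sep, engine=engine, dtype=str,
                            skip_blank_lines=True, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise DsvFormatError("input contains no data") from None

    columns = [str(c).strip().lower() for c in frame.columns]
    seen: dict[str, int] = {}
    for c in columns:
        seen[c] = seen.get(c, 0) + 1
    for required in _REQUIRED:
        if required not in seen:
            raise DsvFormatError(f"missing required column {required.upper()!r}")
        if seen[required] > 1:
            raise DsvFormatError(f"duplicated column {required.upper()!r}")
    extra = [c for c in seen if c not in _REQUIRED]
    if extra:
        raise DsvFormatError(
            f"unexpected extra column(s) {sorted(extra)}; exactly five columns are allowed"
        )
    frame.columns = columns
    if len(frame) == 0:
        raise DsvFormatError("header present but data body is empty")

    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(columns, row))
        name = str(data["study_name"]).strip()
        counts = {f: _coerce_count(data[f], row_number, f.upper()) for f in _COUNT_FIELDS}
        try:
            records.append(StudyRecord(study_name=name, **counts))
        except ValueError as exc:
            raise ValueError(f"row {row_number}: {exc}") from None
    return DTADataset(records)


def write_dsv(dataset: DTADataset, path: Union[str, os.PathLike], delimiter: str = "comma") -> None:
    """Write a dataset back to a delimiter-separated file (round-trips with read_dsv)."""
    if delimiter not in DELIMITERS:
        raise ValueError(f"delimiter must be one of {sorted(DELIMITERS)}, got {delimiter!r}")
    sep = " " if delimiter == "space" else DELIMITERS[delimiter]
    dataset.counts().to_csv(path, sep=sep, index=False)


def validate_dataset(dataset: DTADataset) -> list[str]:
    """Check dataset-level invariants; return non-fatal warnings.

    Raises
    ------
    DatasetValidationError
        If the dataset has fewer than two studies (the hierarchical
        between-study variances are unidentifiable) or duplicated study names.
    """
    if len(dataset) < 2:
        raise DatasetValidationError(
            f"at least 2 studies are required, got {len(dataset)}"
        )
    names = [s.study_name for s in dataset]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DatasetValidationError(f"duplicated study_name value(s): {dupes}")

    warnings: list[str] = []
    if len(dataset) < 5:
        warnings.append(
            f"only {len(dataset)} studies; hierarchical SDs will be poorly identified"
        )
    for s in dataset:
        zero = [f.upper() for f in _COUNT_FIELDS if getattr(s, f) == 0]
        if zero:
            warnings.append(
                f"study {s.study_name!r} has zero cell(s) {zero}; posteriors will be wide"
            )
    return warnings


def example_dataset() -> DTADataset:
    """The packaged 9-study example dataset shipped with the calculator."""
    with resources.files("hsroc.data").joinpath("example_data_set.csv").open("r") as fh:
        return read_dsv(fh, delimiter="comma")
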