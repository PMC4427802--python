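"""The protein x sample intensity matrix and its TSV dialect.

The on-disk dialect is a tab-separated table whose first column holds the
protein identifier, whose header row holds the sample identifiers, and whose
missing quantifications are empty fields (never a sentinel value, which would
be ambiguous with a real zero on the log2 scale).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Normalization stages, in pipeline order.
STAGE_LOG2 = "log2"
STAGE_MEDIAN = "median"
STAGE_RANK = "rank"

PROTEIN_COLUMN = "protein"


class MatrixParseError(ValueError):
    """The file does not conform to the matrix TSV dialect."""


@dataclass(frozen=True)
class IntensityMatrix:
    """Protein x sample table of (possibly missing) intensity values.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein ids with unique sample-id
        columns; values are float64 with NaN marking a missing
        quantification.
    stages
        Normalization stages already applied, in order of application
        (subset of ``("log2", "median", "rank")``).
    """

    data: pd.DataFrame
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        # normalize axis metadata so round-trips through TSV are exact
        self.data.index.name = PROTEIN_COLUMN
        self.data.columns.name = None

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def has_stage(self, stage: str) -> bool:
        return stage in self.stages

    def with_values(self, values: np.ndarray, add_stage: str | None = None) -> "IntensityMatrix":
        """Return a copy with new values (same shape/labels), optionally
        recording one more applied stage."""
        if values.shape != self.data.shape:
            raise ValueError(
                f"shape mismatch: {values.shape} vs {self.data.shape}"
            )
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        stages = self.stages + (add_stage,) if add_stage else self.stages
        return IntensityMatrix(df, stages)

    def restrict(self, proteins: Iterable[str]) -> "IntensityMatrix":
        proteins = list(proteins)
        missing = [p for p in proteins if p not in self.data.index]
        if missing:
            raise KeyError(f"unknown protein ids: {missing}")
        return IntensityMatrix(self.data.loc[proteins], self.stages)


def _scan_tsv(path: Path) -> None:
    """Pre-scan a matrix TSV for structural errors, reporting line numbers."""
    n_fields = None
    seen_ids: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 and not line:
                raise MatrixParseError(f"{path}: line 1: empty header")
            fields = line.split("\t")
            if n_fields is None:
                n_fields = len(fields)
                if n_fields < 2:
                    raise MatrixParseError(
                        f"{path}: line 1: header must hold the protein-id "
                        "column plus at least one sample id"
                    )
                continue
            if len(fields) != n_fields:
                raise MatrixParseError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"found {len(fields)} (ragged row)"
                )
            pid = fields[0]
            if pid in seen_ids:
                raise MatrixParseError(
                    f"{path}: line {lineno}: duplicate protein id {pid!r}"
                )
            seen_ids.add(pid)


def read_matrix(path: str | Path, stages: tuple[str, ...] | None = None) -> IntensityMatrix:
    """Read an intensity matrix from the TSV dialect.

    Empty fields become NaN (missing), never zero.  If ``stages`` is None and
    a ``<path>.meta.json`` sidecar exists, applied normalization stages are
    recovered from it.
    """
    path = Path(path)
    _scan_tsv(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    try:
        values = df.replace("", np.nan).astype(float)
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-numeric value: {exc}") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if stages is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            stages = tuple(meta.get("stages", ()))
        else:
            stages = ()
    return IntensityMatrix(values, tuple(stages))


def write_matrix(matrix: IntensityMatrix, path: str | Path, sidecar: bool = False) -> None:
    """Write the matrix in the TSV dialect (lossless float round-trip).

    With ``sidecar=True`` the applied normalization stages are recorded in a
    ``<path>.meta.json`` file next to the matrix.
    """
    path = Path(path)
    df = matrix.data.copy()
    df.index.name = PROTEIN_COLUMN
    # repr-based float formatting round-trips float64 exactly
    df.to_csv(path, sep="\t", na_rep="")
    if sidecar:
        meta = {"stages": list(matrix.stages)}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )
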