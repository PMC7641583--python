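"""Morphogen parameter tables: CSV loading and validation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

from .comparison import MorphogenRecord

__all__ = ["MorphogenTable", "load_morphogen_table", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("name", "species", "lambda_um", "a_um", "N",
                    "evidence_class")


@dataclass
class MorphogenTable:
    records: list[MorphogenRecord]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("morphogen names must be unique")

    def __iter__(self) -> Iterator[MorphogenRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "name": r.name, "species": r.species, "lambda_um": r.lambda_um,
            "a_um": r.a_um, "N": r.N, "evidence_class": r.evidence_class,
            "lambda_hat": r.lambda_hat,
            "lambda_hat_over_lambda50": r.lambda_hat_over_lambda50,
            "fraction_sdc": r.fraction_sdc, "predicted": r.predicted,
            "provenance": r.provenance,
        } for r in self.records])


def load_morphogen_table(path: str | Path) -> MorphogenTable:
    """Load and validate a morphogen parameter CSV.

    Required columns: name, species, lambda_um, a_um, N, evidence_class; an
    optional free-text ``provenance`` column is carried through.  Malformed
    rows are rejected with messages naming the offending (1-based data) row.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    records = []
    errors = []
    for i, row in df.iterrows():
        try:
            records.append(MorphogenRecord(
                name=str(row["name"]), species=str(row["species"]),
                lambda_um=float(row["lambda_um"]), a_um=float(row["a_um"]),
                N=int(row["N"]), evidence_class=str(row["evidence_class"]),
                provenance=str(row.get("provenance", "") or ""),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 1}: {exc}")
    if errors:
        raise ValueError("invalid morphogen table:\n" + "\n".join(errors))
    return MorphogenTable(records=records)
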