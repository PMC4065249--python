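"""Core domain types shared across the pipeline.

Gene identifiers are plain strings canonicalized to uppercase; conditions
pair a drug token with an optional concentration label; screens are held in
long (tidy) form with one row per replicate measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

DRUGS = ("CPT", "HU", "MMS")
UNTREATED = "UNT"
ALL_DRUG_TOKENS = (UNTREATED,) + DRUGS
DIRECTIONS = ("positive", "negative")

#: column order of the canonical long-format score table
SCORE_COLUMNS = ["query", "array", "drug", "concentration", "replicate", "score"]


def canonical_gene(name: str) -> str:
    """Canonicalize a gene symbol: strip, uppercase; reject empty/whitespace."""
    if name is None:
        raise FormatError("gene name is missing")
    s = str(name).strip().upper()
    if not s or any(c.isspace() for c in s):
        raise FormatError(f"invalid gene name: {name!r}")
    return s


def canonical_drug(token: str) -> str:
    t = str(token).strip().upper()
    aliases = {"UNTREATED": UNTREATED, "NONE": UNTREATED, "YPD": UNTREATED}
    t = aliases.get(t, t)
    if t not in ALL_DRUG_TOKENS:
        raise FormatError(
            f"unknown drug token {token!r}; expected one of {ALL_DRUG_TOKENS}"
        )
    return t


def canonical_direction(token: str) -> str:
    t = str(token).strip().lower()
    aliases = {"pos": "positive", "neg": "negative", "+": "positive", "-": "negative"}
    t = aliases.get(t, t)
    if t not in DIRECTIONS:
        raise FormatError(f"unknown interaction direction {token!r}")
    return t


@dataclass(frozen=True)
class Condition:
    """A screening condition: drug plus optional concentration label.

    Untreated control blocks may carry a label too (screens typically include
    two no-drug control plates); a merged tensor uses ``concentration=None``.
    """

    drug: str
    concentration: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", canonical_drug(self.drug))
        conc = self.concentration
        if conc is not None:
            conc = str(conc).strip()
            if not conc:
                conc = None
        object.__setattr__(self, "concentration", conc)

    @property
    def label(self) -> str:
        if self.concentration is None:
            return self.drug
        return f"{self.drug}@{self.concentration}"


@dataclass(frozen=True)
class InteractionCall:
    """One significant conditional interaction between a query and an array gene."""

    query: str
    array: str
    drug: str
    direction: str
    q: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", canonical_gene(self.query))
        object.__setattr__(self, "array", canonical_gene(self.array))
        drug = canonical_drug(self.drug)
        if drug == UNTREATED:
            raise ConfigurationError("interaction calls are conditional; drug may not be UNT")
        object.__setattr__(self, "drug", drug)
        object.__setattr__(self, "direction", canonical_direction(self.direction))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.query, self.array, self.drug)


@dataclass
class ScreenTensor:
    """Replicate-level S-scores in long form.

    ``data`` has columns query, array, drug, concentration, replicate, score.
    Missing measurements are rows with NaN score (or simply absent rows);
    replicate indices are contiguous from 1 within each
    (query, array, drug, concentration) cell.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"score table lacks required columns: {missing}")
        self.data = self.data[SCORE_COLUMNS].copy()

    @property
    def queries(self) -> list[str]:
        return sorted(self.data["query"].unique())

    @property
    def arrays(self) -> list[str]:
        return sorted(self.data["array"].unique())

    @property
    def conditions(self) -> list[Condition]:
        pairs = (
            self.data[["drug", "concentration"]]
            .drop_duplicates()
            .sort_values(["drug", "concentration"], na_position="first")
        )
        return [
            Condition(d, None if pd.isna(c) else c)
            for d, c in pairs.itertuples(index=False)
        ]

    @property
    def drugs(self) -> list[str]:
        """Drug tokens present, untreated excluded."""
        return [d for d in DRUGS if d in set(self.data["drug"])]

    def replicates(
        self, query: str, array: str, condition: Condition
    ) -> list[float]:
        """Present (non-missing) replicate scores for one cell, replicate order."""
        d = self.data
        mask = (
            (d["query"] == canonical_gene(query))
            & (d["array"] == canonical_gene(array))
            & (d["drug"] == condition.drug)
        )
        if condition.concentration is None:
            mask &= d["concentration"].isna()
        else:
            mask &= d["concentration"] == condition.concentration
        cell = d.loc[mask].sort_values("replicate")
        return [float(s) for s in cell["score"] if not pd.isna(s)]

    def validate(self) -> None:
        """Check tensor invariants; raise on violation."""
        d = self.data
        key_cols = ["query", "array", "drug", "concentration", "replicate"]
        dup = d.duplicated(subset=key_cols)
        if dup.any():
            first = d.loc[dup, key_cols].iloc[0].tolist()
            from .errors import DuplicateRecordError

            raise DuplicateRecordError(f"duplicate measurement key: {first}")
        present = d["score"].dropna()
        if not np.isfinite(present.to_numpy(dtype=float)).all():
            raise FormatError("score table contains non-finite scores")
        if UNTREATED not in set(d["drug"]):
            raise ConfigurationError("screen has no untreated condition")

    def copy(self) -> "ScreenTensor":
        return ScreenTensor(self.data.copy())


def make_tensor(rows: Iterable[tuple]) -> ScreenTensor:
    """Build a ScreenTensor from (query, array, drug, concentration, replicate, score) tuples."""
    df = pd.DataFrame(list(rows), columns=SCORE_COLUMNS)
    df["query"] = df["query"].map(canonical_gene)
    df["array"] = df["array"].map(canonical_gene)
    df["drug"] = df["drug"].map(canonical_drug)
    return ScreenTensor(df)
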