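"""From replicate-level S-scores to significant conditional interaction calls.

The pipeline is: pool drug concentrations into one condition per drug
(doubling the effective replicate count), average replicates into per-cell
mean S-scores, form differential scores D = S_drug − S_untreated per gene
pair, standardize D to Z within a batch, convert Z to two-sided p-values
under a theoretical or robust empirical null, and control the FDR with
Benjamini–Hochberg. Interactions with q below a strict threshold are called,
signed by the direction of D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import benjamini_adjust
from .errors import (
    ConfigurationError,
    DegenerateSpreadError,
    InsufficientDataError,
)
from .types import DRUGS, UNTREATED, InteractionCall, ScreenTensor

NullMethod = Literal["empirical-null", "theoretical-null"]
BatchMode = Literal["per-batch", "pooled"]

#: Normal-consistency factor turning a median absolute deviation into a sigma.
MAD_SCALE = 1.4826

#: published S-score significance thresholds (strict inequalities)
STATIC_LO = -2.4
STATIC_HI = 2.0


@dataclass
class MeanScoreMatrix:
    """Per-cell mean S-scores after replicate averaging.

    ``data`` has one row per (query, array, drug-or-UNT) with columns
    ``S`` (mean over present replicates) and ``n_reps``. Cells with no
    present replicate are absent, never zero-filled.
    """

    data: pd.DataFrame

    def profile(self, query: str, drug: str) -> pd.Series:
        """Mean-score vector over array genes for one (query, condition)."""
        d = self.data
        sel = d[(d["query"] == query) & (d["drug"] == drug)]
        return sel.set_index("array")["S"].sort_index()

    @property
    def queries(self) -> list[str]:
        return sorted(self.data["query"].unique())

    @property
    def drugs(self) -> list[str]:
        return [d for d in DRUGS if d in set(self.data["drug"])]


def merge_concentrations(tensor: ScreenTensor) -> ScreenTensor:
    """Pool each drug's concentrations (and the untreated control blocks)
    into a single condition per drug.

    Replicate lists are concatenated — with the standard design of triplicate
    screens at two concentrations this yields six replicates per cell.
    Cells missing in one concentration contribute only their present
    replicates.
    """
    df = tensor.data.copy()
    # stable order: concentration label then original replicate index
    df = df.sort_values(
        ["query", "array", "drug", "concentration", "replicate"],
        na_position="first",
        kind="mergesort",
    )
    df["replicate"] = df.groupby(["query", "array", "drug"]).cumcount() + 1
    df["concentration"] = np.nan
    return ScreenTensor(df.reset_index(drop=True))


def mean_scores(tensor: ScreenTensor) -> MeanScoreMatrix:
    """Arithmetic mean over present replicates for each (query, array, drug)."""
    df = tensor.data
    grouped = df.groupby(["query", "array", "drug"])["score"].agg(
        S="mean", n_reps="count"
    )
    out = grouped.reset_index()
    out = out[out["n_reps"] >= 1].reset_index(drop=True)
    return MeanScoreMatrix(out)


def differential_scores(
    means: MeanScoreMatrix, query: str, drug: str
) -> pd.Series:
    """D over array genes: mean drug S-score minus mean untreated S-score.

    D is missing wherever either operand is missing.
    """
    if drug == UNTREATED:
        raise ConfigurationError("differential scores are defined against UNT")
    s_drug = means.profile(query, drug)
    s_unt = means.profile(query, UNTREATED)
    if s_unt.empty:
        raise ConfigurationError(f"no untreated profile for query {query}")
    arrays = s_drug.index.union(s_unt.index)
    d = s_drug.reindex(arrays) - s_unt.reindex(arrays)
    d.name = "D"
    return d


def standardize(d: Sequence[float]) -> np.ndarray:
    """Center by the mean and scale by the sample standard deviation (ddof=1).

    Missing values pass through as NaN and are excluded from the moments.
    """
    arr = np.asarray(d, dtype=float)
    present = arr[~np.isnan(arr)]
    if present.size < 3:
        raise InsufficientDataError(
            f"standardization needs >=3 values, got {present.size}"
        )
    sd = present.std(ddof=1)
    if sd == 0:
        raise DegenerateSpreadError("differential scores are constant")
    return (arr - present.mean()) / sd


def estimate_fdr(
    z: Sequence[float], method: NullMethod = "empirical-null"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-values for Z plus Benjamini–Hochberg q-values.

    ``theoretical-null`` takes Z ~ N(0,1): p = 2·Φ(−|Z|). ``empirical-null``
    first re-estimates the null location and scale robustly (median and
    MAD·1.4826) so that a shifted or inflated bulk does not distort the
    tail-area FDR, then applies the same two-sided tail formula.
    """
    z = np.asarray(z, dtype=float)
    present = z[~np.isnan(z)]
    if method == "empirical-null":
        if present.size < 50:
            raise InsufficientDataError(
                f"empirical-null fit needs >=50 values, got {present.size}"
            )
        mu = np.median(present)
        sigma = MAD_SCALE * np.median(np.abs(present - mu))
        if sigma == 0:
            raise DegenerateSpreadError("empirical null has zero spread")
        zz = (z - mu) / sigma
    elif method == "theoretical-null":
        zz = z
    else:
        raise ConfigurationError(f"unknown FDR method {method!r}")
    p = 2.0 * sps.norm.sf(np.abs(zz))
    q = benjamini_adjust(p)
    return p, q


def build_differential_table(
    means: MeanScoreMatrix,
    z_batch: BatchMode = "per-batch",
    fdr_batch: BatchMode = "pooled",
    null_method: NullMethod = "empirical-null",
) -> pd.DataFrame:
    """Assemble the full differential table for every (query, array, drug).

    Standardization runs per (query, drug) vector by default; the FDR
    correction is experiment-wide by default. Pairs missing either the drug
    or the untreated mean are excluded (reported nowhere as q=1).

    Returns a DataFrame with columns query, array, drug, S_drug, S_unt, D,
    Z, p, q, direction.
    """
    pieces = []
    for query in means.queries:
        s_unt = means.profile(query, UNTREATED)
        if s_unt.empty:
            raise ConfigurationError(f"no untreated profile for query {query}")
        for drug in means.drugs:
            s_drug = means.profile(query, drug)
            common = s_drug.index.intersection(s_unt.index)
            if common.empty:
                continue
            piece = pd.DataFrame(
                {
                    "query": query,
                    "array": common,
                    "drug": drug,
                    "S_drug": s_drug.loc[common].to_numpy(),
                    "S_unt": s_unt.loc[common].to_numpy(),
                }
            )
            piece["D"] = piece["S_drug"] - piece["S_unt"]
            pieces.append(piece)
    if not pieces:
        raise InsufficientDataError("no testable (query, drug) pairs")
    table = pd.concat(pieces, ignore_index=True)

    if z_batch == "per-batch":
        table["Z"] = (
            table.groupby(["query", "drug"])["D"]
            .transform(lambda d: standardize(d.to_numpy()))
        )
    elif z_batch == "pooled":
        table["Z"] = standardize(table["D"].to_numpy())
    else:
        raise ConfigurationError(f"unknown z_batch mode {z_batch!r}")

    if fdr_batch == "pooled":
        p, q = estimate_fdr(table["Z"].to_numpy(), null_method)
        table["p"], table["q"] = p, q
    elif fdr_batch == "per-batch":
        table["p"] = np.nan
        table["q"] = np.nan
        for _, idx in table.groupby(["query", "drug"]).groups.items():
            p, q = estimate_fdr(table.loc[idx, "Z"].to_numpy(), null_method)
            table.loc[idx, "p"] = p
            table.loc[idx, "q"] = q
    else:
        raise ConfigurationError(f"unknown fdr_batch mode {fdr_batch!r}")

    table["direction"] = np.where(table["D"] > 0, "positive", "negative")
    table.loc[table["D"] == 0, "direction"] = "none"
    return table


def call_significant(
    table: pd.DataFrame, alpha: float = 0.05
) -> list[InteractionCall]:
    """Calls with q strictly below alpha; D = 0 rows are never called."""
    if table.empty:
        return []
    hits = table[(table["q"] < alpha) & (table["D"] != 0)]
    return [
        InteractionCall(
            query=r.query, array=r.array, drug=r.drug,
            direction="positive" if r.D > 0 else "negative", q=float(r.q),
        )
        for r in hits.itertuples(index=False)
    ]


def static_threshold_calls(
    means: MeanScoreMatrix, lo: float = STATIC_LO, hi: float = STATIC_HI
) -> pd.DataFrame:
    """Per-condition significant interactions by the fixed S-score thresholds.

    Negative where S < lo, positive where S > hi (strict on both sides);
    includes the untreated condition. Used for distribution summaries, not
    for the conditional network.
    """
    if lo >= hi:
        raise ConfigurationError(f"lo must be < hi (got {lo} >= {hi})")
    d = means.data
    out = d[(d["S"] < lo) | (d["S"] > hi)].copy()
    out["direction"] = np.where(out["S"] > hi, "positive", "negative")
    return out.reset_index(drop=True)
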