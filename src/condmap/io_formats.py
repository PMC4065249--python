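"""Readers and writers for every external representation the pipeline touches.

The canonical score format is a long (tidy) TSV with one row per replicate
measurement: ``query  array  drug  concentration  replicate  score``.
Interaction networks are exported as SIF or as an edge-attribute table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CondmapError, DuplicateRecordError, FormatError
from .types import (
    SCORE_COLUMNS,
    UNTREATED,
    InteractionCall,
    ScreenTensor,
    canonical_direction,
    canonical_drug,
    canonical_gene,
)

PathLike = Union[str, Path]

#: packaged transcription of the published significant-interaction table
BUNDLED_CALLS = "conditional_interactions.tsv"


@dataclass
class AnnotationSet:
    """Term -> gene-set mapping restricted to a background universe."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    @property
    def n_background(self) -> int:
        return len(self.background)


def read_scores_long(
    path: PathLike, dialect: Optional[Mapping[str, str]] = None
) -> ScreenTensor:
    """Read a long-format replicate-level score table.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    dialect:
        Optional mapping from canonical column names (``query``, ``array``,
        ``drug``, ``concentration``, ``replicate``, ``score``) to the column
        names actually used in the file, so foreign layouts can be adapted
        without code changes.

    Empty or ``NA`` scores are recorded as missing cells. Duplicate
    (query, array, drug, concentration, replicate) keys raise
    :class:`DuplicateRecordError`.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    rename = {dialect.get(c, c): c for c in SCORE_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"present: {list(df.columns)}"
        )
    df = df[SCORE_COLUMNS].copy()

    df["query"] = df["query"].map(canonical_gene)
    df["array"] = df["array"].map(canonical_gene)
    df["drug"] = df["drug"].map(canonical_drug)
    df["concentration"] = df["concentration"].where(
        ~df["concentration"].isin(["", "NA", "NaN", "nan", "None"]), other=np.nan
    )

    try:
        df["replicate"] = df["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer replicate index ({exc})") from exc

    na_tokens = {"", "NA", "NAN", "NONE", "NULL", "."}
    scores = []
    for i, raw in enumerate(df["score"]):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip().upper() in na_tokens:
            scores.append(np.nan)
            continue
        try:
            scores.append(float(raw))
        except ValueError as exc:
            # +2: one for the header row, one for 0- vs 1-based counting
            raise FormatError(
                f"{path}: non-numeric score {raw!r} on line {i + 2}"
            ) from exc
    df["score"] = scores

    key_cols = ["query", "array", "drug", "concentration", "replicate"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise DuplicateRecordError(f"{path}: duplicate measurement key {first}")
    return ScreenTensor(df)


def write_scores_long(tensor: ScreenTensor, path: PathLike) -> None:
    """Write a ScreenTensor in the canonical long TSV; NaN scores become ``NA``."""
    df = tensor.data.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_interaction_calls(path: Optional[PathLike] = None) -> list[InteractionCall]:
    """Read a significant-interaction table (query, drug, interaction, gene).

    With no ``path``, reads the packaged transcription of the published
    summary table of significant conditional interactions.
    """
    if path is None:
        ref = resources.files("condmap.data").joinpath(BUNDLED_CALLS)
        with resources.as_file(ref) as p:
            return read_interaction_calls(p)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["query", "drug", "interaction", "gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            InteractionCall(
                query=row.query,
                array=row.gene,
                drug=row.drug,
                direction=row.interaction,
            )
        )
    return calls


# read_table1_fixture is the contract name used in the original analysis plan
read_table1_fixture = read_interaction_calls


def read_annotations(
    path: PathLike, background_path: Optional[PathLike] = None
) -> AnnotationSet:
    """Read a two-column term↦gene TSV, optionally restricted to a background list.

    Genes annotated but absent from an explicit background are dropped with a
    warning. Without a background file the background is the set of annotated
    genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns (term, gene)")
    # tolerate a header row
    if str(df.iloc[0, 0]).strip().lower() in {"term", "term_id", "go_term"}:
        df = df.iloc[1:]
    pairs = [(str(t).strip(), canonical_gene(g)) for t, g in df.iloc[:, :2].itertuples(index=False)]

    if background_path is not None:
        bg_genes = []
        for line in Path(background_path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                bg_genes.append(canonical_gene(line))
        background = frozenset(bg_genes)
        dropped = sorted({g for _, g in pairs if g not in background})
        if dropped:
            warnings.warn(
                f"{len(dropped)} annotated gene(s) absent from background dropped: "
                f"{', '.join(dropped[:10])}{'...' if len(dropped) > 10 else ''}",
                stacklevel=2,
            )
        pairs = [(t, g) for t, g in pairs if g in background]
    else:
        background = frozenset(g for _, g in pairs)

    terms: dict[str, set[str]] = {}
    for t, g in pairs:
        terms.setdefault(t, set()).add(g)
    return AnnotationSet(
        terms={t: frozenset(gs) for t, gs in terms.items()}, background=background
    )


def _relation(drug: str, direction: str) -> str:
    return f"{drug}_{'pos' if direction == 'positive' else 'neg'}"


def parse_relation(rel: str) -> tuple[str, str]:
    try:
        drug, sign = rel.rsplit("_", 1)
        return canonical_drug(drug), canonical_direction(sign)
    except (ValueError, FormatError) as exc:
        raise FormatError(f"unparseable relation token {rel!r}") from exc


def write_network(
    network: nx.Graph, path: PathLike, format: str = "sif"
) -> None:
    """Export an interaction network as SIF or as an edge-attribute table.

    SIF lines are ``query <TAB> DRUG_sign <TAB> array``, one per edge
    annotation. The edge-table variant adds ``direction`` and ``q`` columns
    and can be read back with :func:`read_edge_table`.
    """
    if network.number_of_edges() == 0:
        raise CondmapError("refusing to write an empty network")
    if format not in {"sif", "edge-table"}:
        raise ValueError(f"unknown network format {format!r}")

    lines = []
    for u, v, attrs in network.edges(data=True):
        if network.nodes[u].get("role") == "query":
            q, a = u, v
        else:
            q, a = v, u
        for drug, direction in sorted(attrs["annotations"]):
            qval = attrs.get("q", {}).get((drug, direction))
            lines.append((q, a, drug, direction, qval))
    lines.sort()

    with open(path, "w") as fh:
        if format == "sif":
            for q, a, drug, direction, _ in lines:
                fh.write(f"{q}\t{_relation(drug, direction)}\t{a}\n")
        else:
            fh.write("query\tarray\tdrug\tdirection\tq\n")
            for q, a, drug, direction, qval in lines:
                qs = "NA" if qval is None else f"{qval:.6g}"
                fh.write(f"{q}\t{a}\t{drug}\t{direction}\t{qs}\n")


def read_edge_table(path: PathLike) -> list[InteractionCall]:
    """Read back an edge-table network export as interaction calls."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    calls = []
    for row in df.itertuples(index=False):
        q = None if row.q in (None, "NA") or pd.isna(row.q) else float(row.q)
        calls.append(
            InteractionCall(
                query=row.query, array=row.array, drug=row.drug,
                direction=row.direction, q=q,
            )
        )
    return calls


def write_calls(calls: Sequence[InteractionCall], path: PathLike) -> None:
    """Write interaction calls as TSV (query, drug, interaction, gene, q)."""
    with open(path, "w") as fh:
        fh.write("query\tdrug\tinteraction\tgene\tq\n")
        for c in sorted(calls, key=lambda c: (c.query, c.drug, c.direction, c.array)):
            qs = "NA" if c.q is None else f"{c.q:.6g}"
            fh.write(f"{c.query}\t{c.drug}\t{c.direction.capitalize()}\t{c.array}\t{qs}\n")
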