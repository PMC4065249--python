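"""Term enrichment of gene lists against a screened background.

Plain hypergeometric upper-tail test per term with Benjamini–Hochberg
correction across all tested terms. The background defaults to the screened
array-gene list rather than the whole genome, so enrichment reflects the
library composition actually sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import benjamini_adjust
from .errors import CondmapError
from .io_formats import AnnotationSet

__all__ = ["AnnotationSet", "EnrichmentRow", "enrich", "benjamini_adjust"]

LOW_POWER_TERM_SIZE = 2


@dataclass
class EnrichmentRow:
    term: str
    k: int      # hits in the query list
    n: int      # query-list size within background
    K: int      # term size in background
    N: int      # background size
    fold: float
    p: float
    q: float
    significant: bool
    low_power: bool


def enrich(
    genes: set[str], annotations: AnnotationSet, alpha: float = 0.05
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of ``genes`` over every annotated term.

    Genes outside the background are dropped (their count is recoverable as
    ``len(genes) - n``). p = P(X >= k) for X ~ Hypergeom(N, K, n);
    fold = (k/n)/(K/N). Terms with K < 2 are tested but flagged low-power.
    """
    if not annotations.background:
        raise CondmapError("annotation background is empty")
    in_bg = genes & annotations.background
    if not in_bg:
        raise CondmapError("no query gene overlaps the annotation background")
    n = len(in_bg)
    N = annotations.n_background

    terms = sorted(t for t, gs in annotations.terms.items() if len(gs) >= 1)
    ks = np.array([len(annotations.terms[t] & in_bg) for t in terms])
    Ks = np.array([len(annotations.terms[t]) for t in terms])
    p = sps.hypergeom.sf(ks - 1, N, Ks, n)
    p = np.minimum(p, 1.0)
    q = benjamini_adjust(p)

    rows = []
    for term, k, K, pi, qi in zip(terms, ks, Ks, p, q):
        fold = (k / n) / (K / N)
        rows.append(
            EnrichmentRow(
                term=term, k=int(k), n=n, K=int(K), N=N,
                fold=float(fold), p=float(pi), q=float(qi),
                significant=bool(qi < alpha),
                low_power=bool(K < LOW_POWER_TERM_SIZE),
            )
        )
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view of enrichment results (column order matches the TSV export)."""
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "fold": r.fold, "p": r.p, "q": r.q, "significant": r.significant,
            }
            for r in rows
        ]
    )
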