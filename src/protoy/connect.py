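"""Connection scores against the Obp56h seed set and Fisher enrichments.

The connection score of transcript i against a seed gene family is

    C_i = sum_j a_ij * |F_j|

over seed genes j, where ``a_ij`` is the soft-thresholded network
adjacency and ``F_j`` the seed gene's log2 fold-change between male
types: transcripts tightly connected to the most differentially
expressed seed genes score highest.  Ranked scores define "central
genes" (top 100 by convention), which are then tested for chromosome
enrichment with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult

__all__ = [
    "connection_scores",
    "central_genes",
    "fisher_exact",
    "chromosome_enrichment",
    "sign_enrichment",
    "FisherResult",
]


def connection_scores(
    adj: pd.DataFrame, seed_genes, fold_changes: DEResult | pd.Series
) -> pd.DataFrame:
    """Connection score ``C_i = sum_j a_ij |F_j|`` over the seed set.

    Seed genes are excluded from their own ranking (the statistic asks
    which *other* transcripts covary with the family), and a transcript's
    self-adjacency is never used.  Returns a DataFrame with columns
    ``score`` and ``rank`` (descending score, ties broken by ascending
    gene ID).
    """
    fc = fold_changes.log2fc if isinstance(fold_changes, DEResult) else fold_changes
    seeds = sorted(set(seed_genes))
    if not seeds:
        raise ValueError("seed gene set is empty")
    missing = [s for s in seeds if s not in adj.index]
    if missing:
        raise KeyError(f"seed genes absent from adjacency: {missing}")
    missing_fc = [s for s in seeds if s not in fc.index]
    if missing_fc:
        raise KeyError(f"seed genes missing a fold-change: {missing_fc}")
    others = [g for g in adj.index if g not in set(seeds)]
    weights = fc.loc[seeds].abs().to_numpy()
    scores = adj.loc[others, seeds].to_numpy() @ weights
    out = pd.DataFrame({"score": scores}, index=pd.Index(others, name="gene"))
    order = sorted(range(len(others)), key=lambda i: (-scores[i], others[i]))
    ranks = np.empty(len(others), dtype=int)
    ranks[order] = np.arange(1, len(others) + 1)
    out["rank"] = ranks
    return out


def central_genes(
    scores: pd.DataFrame, k: int | None = None, top_fraction: float | None = None
) -> list[str]:
    """The k highest-scoring genes (ties by ascending ID).

    ``top_fraction`` mode takes the nearest integer to ``fraction * n``
    (at least 1), so a percentage printed to two decimals inverts back to
    the count it came from — e.g. the top 0.55% of 18,182 ranked
    transcripts is 100 genes.  At most one of ``k`` and ``top_fraction``
    may be given; the default is the top 100.
    """
    if k is not None and top_fraction is not None:
        raise ValueError("give either k or top_fraction, not both")
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        k = max(1, math.floor(top_fraction * len(scores) + 0.5))
    elif k is None:
        k = 100
    if k > len(scores):
        raise ValueError("k exceeds the number of scored genes")
    ordered = scores.sort_values(["rank"]).index
    return list(ordered[:k])


@dataclass
class FisherResult:
    """A 2x2 Fisher test: table, sample odds ratio, two-sided p."""

    table: np.ndarray
    odds_ratio: float
    p: float
    degenerate: bool = False


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    The two-sided p is the sum of hypergeometric probabilities of tables
    (at fixed margins) no more probable than the observed one.  The sample
    odds ratio ``ad/bc`` is reported with 0/inf conventions for zero
    cells; a zero margin gives p = 1 with the odds ratio flagged
    undefined.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("table must hold non-negative integers")
        t = t.astype(int)
    a, b, c, d = t.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(table=t, odds_ratio=np.nan, p=1.0, degenerate=True)
    if b * c == 0:
        oratio = np.inf if a * d > 0 else np.nan
    else:
        oratio = (a * d) / (b * c)
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return FisherResult(table=t, odds_ratio=float(oratio), p=min(p, 1.0))


def chromosome_enrichment(
    geneset, annotation: pd.Series, focal: str
) -> FisherResult:
    """Fisher enrichment of a gene set on a focal chromosome.

    ``annotation`` maps gene -> chromosome over the analysis universe;
    genes with a missing/empty chromosome are excluded from the universe
    (matching the convention of counting only placed genes).  Builds the
    (in-set/out-set x focal/other) table and delegates to
    :func:`fisher_exact`.
    """
    ann = annotation.dropna()
    ann = ann[ann.astype(str) != ""]
    if focal not in set(ann.astype(str)):
        raise ValueError(f"focal chromosome {focal!r} absent from annotation")
    genes = ann.index
    in_set = genes.isin(set(geneset))
    on_focal = ann.astype(str).to_numpy() == focal
    table = np.array(
        [
            [int((in_set & on_focal).sum()), int((in_set & ~on_focal).sum())],
            [int((~in_set & on_focal).sum()), int((~in_set & ~on_focal).sum())],
        ]
    )
    return fisher_exact(table)


def sign_enrichment(fold_changes: DEResult | pd.Series, family) -> FisherResult:
    """Fisher test of fold-change sign for a gene family vs the background.

    Tests whether the family is enriched for genes with higher expression
    in Y^M males (negative III^M - Y^M fold-change), regardless of
    significance.  ``F = 0`` counts as "not higher in Y^M" (conservative).
    """
    fc = fold_changes.log2fc if isinstance(fold_changes, DEResult) else fold_changes
    family = sorted(set(family))
    if not family:
        raise ValueError("family gene set is empty")
    missing = [g for g in family if g not in fc.index]
    if missing:
        raise KeyError(f"family genes missing a fold-change: {missing}")
    is_family = fc.index.isin(set(family))
    higher_ym = fc.to_numpy() < 0.0
    table = np.array(
        [
            [int((is_family & higher_ym).sum()), int((is_family & ~higher_ym).sum())],
            [int((~is_family & higher_ym).sum()), int((~is_family & ~higher_ym).sum())],
        ]
    )
    return fisher_exact(table)
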