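"""Cross-species comparisons: resampling fold-change nulls and per-tissue
expression normalization.

The resampling null asks whether an ortholog set's mean log2 fold-change
is more extreme than expected for a same-size random draw from the
genome-wide fold-change distribution: 10,000 subsets without replacement
by convention, one-tailed in the direction of the observed set.  The
tissue normalization divides each gene's expression by the mean over all
included genes in that tissue sample so heterogeneous platforms (RPKM,
TPM, microarray intensity) can be placed on one comparative scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "resample_fold_change_null",
    "normalize_tissue_expression",
    "ortholog_direction_test",
]


def resample_fold_change_null(
    observed_ids,
    all_fc: pd.Series,
    n_subsets: int = 10_000,
    tail: str | None = None,
    seed: int = 0,
    plus_one: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo p for an ortholog set's mean log2 fold-change.

    Draws ``n_subsets`` subsets of size ``len(observed_ids)`` without
    replacement from the fold-change values and reports the proportion
    whose mean is strictly more extreme than the observed mean in the
    stated tail (``lower``, ``upper`` or ``two_sided`` on |mean|).  With
    ``tail=None`` the tail is taken from the sign of the observed mean;
    an exactly-zero mean then has no direction and is an error.
    ``plus_one`` applies the (r+1)/(n+1) small-sample correction (off by
    default).

    Returns ``(observed_mean, p)``.
    """
    observed_ids = list(observed_ids)
    if not observed_ids:
        raise ValueError("observed gene set is empty")
    missing = [g for g in observed_ids if g not in all_fc.index]
    if missing:
        raise KeyError(f"observed genes missing from the background: {missing}")
    values = all_fc.to_numpy(dtype=float)
    k = len(observed_ids)
    if k > len(values):
        raise ValueError("observed set larger than the background")
    observed_mean = float(all_fc.loc[observed_ids].mean())
    if tail is None:
        if observed_mean == 0.0:
            raise ValueError("observed mean is 0: specify the tail explicitly")
        tail = "lower" if observed_mean < 0 else "upper"
    if tail not in {"lower", "upper", "two_sided"}:
        raise ValueError("tail must be 'lower', 'upper' or 'two_sided'")

    rng = np.random.Generator(np.random.Philox(seed))
    n = len(values)
    means = np.empty(n_subsets)
    for b in range(n_subsets):
        means[b] = values[rng.choice(n, size=k, replace=False)].mean()
    if tail == "lower":
        more_extreme = int((means < observed_mean).sum())
    elif tail == "upper":
        more_extreme = int((means > observed_mean).sum())
    else:
        more_extreme = int((np.abs(means) > abs(observed_mean)).sum())
    if plus_one:
        p = (more_extreme + 1) / (n_subsets + 1)
    else:
        p = more_extreme / n_subsets
    return observed_mean, float(p)


def normalize_tissue_expression(
    table: pd.DataFrame,
    min_replicates: int = 4,
) -> pd.DataFrame:
    """Per-tissue mean normalization of heterogeneous expression levels.

    ``table`` needs columns ``gene, tissue, value`` and optionally
    ``transcript``, ``n_replicates`` (microarray detection count) and
    ``status``.  Entries are excluded — with the reason recorded — when
    the value is 0, the replicate count is below ``min_replicates``, or
    the status is not ``OK``.  Multi-transcript genes are averaged to a
    gene-level value first; the per-tissue mean is computed over included
    genes only and ``normalized = value / tissue_mean``.
    """
    t = table.copy()
    reason = pd.Series("", index=t.index, dtype=object)
    reason[t["value"] == 0] = "zero value"
    if "n_replicates" in t.columns:
        low = (t["n_replicates"].notna()) & (t["n_replicates"] < min_replicates)
        reason[low & (reason == "")] = "detected in too few replicates"
    if "status" in t.columns:
        bad = t["status"].notna() & (t["status"] != "OK")
        reason[bad & (reason == "")] = "failed platform threshold"
    t["excluded_reason"] = reason
    included = t[reason == ""]

    # transcript-level measurements collapse to the gene mean
    gene_level = (
        included.groupby(["tissue", "gene"], as_index=False)["value"].mean()
    )
    out_rows = []
    for tissue, sub in gene_level.groupby("tissue"):
        if sub.empty:
            raise ValueError(f"tissue {tissue!r} has no included genes")
        mean = sub["value"].mean()
        sub = sub.assign(tissue_mean=mean, normalized=sub["value"] / mean)
        out_rows.append(sub)
    tissues_seen = set(gene_level["tissue"])
    for tissue in set(t["tissue"]) - tissues_seen:
        raise ValueError(f"tissue {tissue!r} has no included genes")
    normalized = pd.concat(out_rows, ignore_index=True)
    excluded = t.loc[reason != "", ["gene", "tissue", "value", "excluded_reason"]]
    normalized = normalized.merge(
        excluded.assign(marker=True)[["gene", "tissue", "marker"]],
        on=["gene", "tissue"], how="left",
    ).drop(columns="marker")
    normalized.attrs["excluded"] = excluded.reset_index(drop=True)
    return normalized


def ortholog_direction_test(
    orthologs: pd.DataFrame,
    all_fc: pd.Series,
    direction: str,
    n_subsets: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> tuple[float, float]:
    """Resampling test for one knockdown-direction ortholog subset.

    ``orthologs`` needs columns ``mdom_id`` and ``direction`` (``up`` or
    ``down`` in the knockdown experiment).  The subset size is taken from
    the table, never from configuration; ``up`` genes are tested for an
    excess of positive fold-changes (upper tail), ``down`` genes for an
    excess of negative fold-changes (lower tail).
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    ids = orthologs.loc[orthologs["direction"] == direction, "mdom_id"].tolist()
    if not ids:
        raise ValueError(f"no orthologs with direction {direction!r}")
    tail = "upper" if direction == "up" else "lower"
    return resample_fold_change_null(
        ids, all_fc, n_subsets=n_subsets, tail=tail, seed=seed, plus_one=plus_one
    )
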