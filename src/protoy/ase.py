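"""Allele-specific expression at diagnostic SNPs.

III^M males are heterozygous for a III^M and a standard chromosome III
allele; Y^M males carry two standard III alleles.  Sites heterozygous in
every III^M group and homozygous in every Y^M group are diagnostic: the
allele absent from Y^M genotypes is assigned to the III^M chromosome.
Per-site read depths are normalized to fragments per million (FPM =
depth / total mapped reads x 10^6) and compared with Wilcoxon rank-sum
tests in three pairwise contrasts per site:

* ``IIIM-III``  — III^M vs III allele within III^M males,
* ``IIIM-YM``   — III^M allele in III^M males vs both III alleles in Y^M males,
* ``III-YM``    — III allele in III^M males vs both III alleles in Y^M males.

The default rank-sum variant is the normal approximation without
continuity correction, which for complete separation of two groups of
four gives p = 2 * Phi(-8/sqrt(12)) ~ 0.021; the exact enumeration
variant (p = 2/70 ~ 0.029 in the same configuration) is provided and
preferable for new data.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "select_diagnostic_snps",
    "normalize_depth_fpm",
    "compare_alleles",
    "flag_monoallelic",
    "COMPARISONS",
]

logger = logging.getLogger(__name__)

COMPARISONS = ("IIIM-III", "IIIM-YM", "III-YM")


def select_diagnostic_snps(calls: pd.DataFrame) -> pd.DataFrame:
    """Select sites heterozygous in III^M males and homozygous in Y^M males.

    ``calls`` needs columns ``scaffold, pos, group, genotype, call`` where
    ``call`` is an unordered diploid genotype like ``"A/G"``.  A site is
    kept when every III^M group is heterozygous (same two alleles), every
    Y^M group is homozygous, and the Y^M allele is one of the two III^M
    alleles; the other allele is assigned to the III^M chromosome.  Sites
    with conflicting Y^M homozygous calls across groups are dropped with a
    log entry.

    Returns one row per selected site: scaffold, pos, iiim_allele,
    iii_allele.
    """
    required = {"scaffold", "pos", "group", "genotype", "call"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    rows = []
    for (scaffold, pos), site in calls.groupby(["scaffold", "pos"], sort=True):
        het_sets = []
        ok = True
        for call in site.loc[site["genotype"] == "IIIM", "call"]:
            alleles = frozenset(call.split("/"))
            if len(alleles) != 2:
                ok = False
                break
            het_sets.append(alleles)
        if not ok or not het_sets or len(set(het_sets)) != 1:
            continue
        hom_alleles = set()
        for call in site.loc[site["genotype"] == "YM", "call"]:
            alleles = set(call.split("/"))
            if len(alleles) != 1:
                ok = False
                break
            hom_alleles |= alleles
        if not ok or not hom_alleles:
            continue
        if len(hom_alleles) != 1:
            logger.info("site %s:%s dropped: conflicting YM homozygous alleles %s",
                        scaffold, pos, sorted(hom_alleles))
            continue
        iii = next(iter(hom_alleles))
        het = set(het_sets[0])
        if iii not in het:
            continue
        iiim = next(iter(het - {iii}))
        rows.append({"scaffold": scaffold, "pos": pos, "iiim_allele": iiim, "iii_allele": iii})
    return pd.DataFrame(rows, columns=["scaffold", "pos", "iiim_allele", "iii_allele"])


def normalize_depth_fpm(table: pd.DataFrame) -> pd.DataFrame:
    """Populate the FPM column: ``depth / library_size * 1e6``.

    Raw depths are retained.  A zero library size is an error naming the
    offending group.
    """
    bad = table.loc[table["library_size"] <= 0, "group"].unique()
    if len(bad):
        raise ValueError(f"non-positive library size for group(s): {sorted(map(str, bad))}")
    out = table.copy()
    out["fpm"] = out["depth"] / out["library_size"] * 1e6
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "normal_approx":
        res = stats.ranksums(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # report the rank-sum z-equivalent statistic direction via U
        u = float(res.statistic)
        mean_u = len(x) * len(y) / 2.0
        return u - mean_u, float(res.pvalue)
    raise ValueError("method must be 'normal_approx' or 'exact'")


def compare_alleles(table: pd.DataFrame, method: str = "normal_approx") -> pd.DataFrame:
    """Rank-sum tests of allele-specific FPM, three comparisons per site.

    ``table`` is a tidy (scaffold, pos, allele, group, genotype, depth,
    library_size[, fpm]) frame; FPM is computed if absent.  Observations
    are per strain-by-batch group: the III^M-allele and III-allele FPM
    within III^M groups, and the total (both III alleles) FPM per Y^M
    group.  Returns one row per site x comparison with the statistic,
    two-sided p and a significance flag at 0.05.
    """
    if "fpm" not in table.columns:
        table = normalize_depth_fpm(table)
    rows = []
    for (scaffold, pos), site in table.groupby(["scaffold", "pos"], sort=True):
        iiim_groups = site[site["genotype"] == "IIIM"]
        ym_groups = site[site["genotype"] == "YM"]
        m = iiim_groups[iiim_groups["allele"] == "IIIM"].set_index("group")["fpm"]
        i = iiim_groups[iiim_groups["allele"] == "III"].set_index("group")["fpm"]
        y = ym_groups.groupby("group")["fpm"].sum()
        if m.empty or i.empty or y.empty:
            logger.info("site %s:%s skipped: missing group depths", scaffold, pos)
            continue
        if len(m) != 4 or len(y) != 4:
            warnings.warn(
                f"site {scaffold}:{pos}: expected 4 IIIM and 4 YM groups, "
                f"got {len(m)} and {len(y)}",
                stacklevel=2,
            )
        pairs = {
            "IIIM-III": (m.to_numpy(), i.reindex(m.index).to_numpy()),
            "IIIM-YM": (m.to_numpy(), y.to_numpy()),
            "III-YM": (i.to_numpy(), y.to_numpy()),
        }
        for comp, (x1, x2) in pairs.items():
            if np.any(np.isnan(x1)) or np.any(np.isnan(x2)):
                logger.info("site %s:%s %s skipped: missing depths", scaffold, pos, comp)
                continue
            stat, p = _ranksum_p(x1, x2, method)
            rows.append(
                {
                    "scaffold": scaffold,
                    "pos": pos,
                    "comparison": comp,
                    "statistic": stat,
                    "p": p,
                    "significant": p < 0.05,
                }
            )
    return pd.DataFrame(
        rows, columns=["scaffold", "pos", "comparison", "statistic", "p", "significant"]
    )


def flag_monoallelic(table: pd.DataFrame) -> pd.Series:
    """Flag sites with complete III^M-allele bias in every III^M group.

    True iff the III-allele raw depth is exactly 0 in every III^M group
    while the III^M-allele depth is positive in every III^M group — the
    pattern suggestive of monoallelic expression of the III^M allele.
    """
    flags = {}
    for (scaffold, pos), site in table.groupby(["scaffold", "pos"], sort=True):
        sub = site[site["genotype"] == "IIIM"]
        iii = sub.loc[sub["allele"] == "III", "depth"]
        iiim = sub.loc[sub["allele"] == "IIIM", "depth"]
        flags[(scaffold, pos)] = bool(
            len(iii) and len(iiim) and (iii == 0).all() and (iiim > 0).all()
        )
    idx = pd.MultiIndex.from_tuples(flags.keys(), names=["scaffold", "pos"])
    return pd.Series(list(flags.values()), index=idx, name="monoallelic")
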