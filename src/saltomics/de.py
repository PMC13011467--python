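"""Differential-expression and salt-responsiveness calling rules.

Inputs are per-gene log2 fold changes (lfc) versus a preculture reference
and BH-adjusted p-values, one pair of columns per culture condition
(two salinity levels x three time points). The rules are:

* zeroing     — an lfc is set to 0 where its adjusted p >= 0.05 (or is
                missing), i.e. non-significant changes count as "no
                change";
* DE call     — a gene is differentially expressed if the span between
                its highest and lowest expression level across the seven
                conditions (six columns plus the reference at lfc 0) is
                at least 5-fold, i.e. max - min >= log2(5) on the log2
                scale;
* salt class  — among DE genes only: compare the maximum lfc over the
                salt columns (M+) with the maximum over the no-salt
                columns (M-); salt_up iff M+ - M- >= log2(5), salt_down
                iff M- - M+ >= log2(5), else neither;
* enrichment  — two-sided Fisher's exact test of each functional
                category in the DE set versus the annotated background,
                BH-adjusted across categories;
* conservation— histogram of ortholog-conservation fractions (0..1) in
                equal-width bins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError
from .stats import bh_adjust

logger = logging.getLogger(__name__)

SALT_CONDITIONS = ("salt_t1", "salt_t2", "salt_t3")
NO_SALT_CONDITIONS = ("no_salt_t1", "no_salt_t2", "no_salt_t3")
CONDITIONS = SALT_CONDITIONS + NO_SALT_CONDITIONS


def lfc_columns(conditions=CONDITIONS) -> list[str]:
    return [f"{c}_lfc" for c in conditions]


def padj_columns(conditions=CONDITIONS) -> list[str]:
    return [f"{c}_padj" for c in conditions]


def zero_nonsignificant(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Return the lfc matrix with non-significant entries set to 0.

    ``table`` is indexed by gene_id with ``<cond>_lfc`` / ``<cond>_padj``
    column pairs. Missing padj is treated as >= alpha (zeroed).
    """
    lfc = table[lfc_columns()].copy()
    lfc.columns = list(CONDITIONS)
    padj = table[padj_columns()].copy()
    padj.columns = list(CONDITIONS)
    vals = padj.to_numpy(dtype=float)
    finite = ~np.isnan(vals)
    if (vals[finite] < 0).any() or (vals[finite] > 1).any():
        raise InvalidInputError("adjusted p-values must lie in [0, 1]")
    keep = finite & (vals < alpha)
    return lfc.where(keep, 0.0)


def call_differential_genes(zeroed: pd.DataFrame, fold: float = 5.0) -> pd.Series:
    """DE iff the lfc span over the 7 conditions (reference = 0) >= log2(fold)."""
    hi = np.maximum(zeroed.max(axis=1), 0.0)
    lo = np.minimum(zeroed.min(axis=1), 0.0)
    return (hi - lo) >= np.log2(fold)


def call_salinity_responsive(
    zeroed: pd.DataFrame, de_flags: pd.Series, fold: float = 5.0
) -> pd.Series:
    """Classify DE genes as salt_up / salt_down / neither (max-of-max rule).

    Non-DE genes get pd.NA: the salinity rule is only evaluated on genes
    already called differentially expressed.
    """
    m_plus = zeroed[list(SALT_CONDITIONS)].max(axis=1)
    m_minus = zeroed[list(NO_SALT_CONDITIONS)].max(axis=1)
    log_fold = np.log2(fold)
    cls = pd.Series("neither", index=zeroed.index, dtype=object)
    cls[m_plus - m_minus >= log_fold] = "salt_up"
    cls[m_minus - m_plus >= log_fold] = "salt_down"
    cls[~de_flags.reindex(zeroed.index).fillna(False).astype(bool)] = pd.NA
    return cls


def enrichment_test(
    de_genes, annotation: pd.DataFrame, background=None
) -> pd.DataFrame:
    """Two-sided Fisher's exact gene-set enrichment of the DE set.

    ``annotation`` has columns ``gene_id`` and ``category`` (a gene may
    carry several categories). The background defaults to all annotated
    genes. For each category with k DE members out of n DE genes and K
    background members out of N background genes, reports
    fold_enrichment = (k/n)/(K/N), the two-sided Fisher p on the 2x2
    table (k, n-k, K-k, N-n-K+k) and the BH q across categories.
    """
    de_genes = set(de_genes)
    if background is None:
        background = set(annotation["gene_id"])
    else:
        background = set(background)
    missing = de_genes - background
    if missing:
        raise InvalidInputError(f"{len(missing)} DE genes absent from background")
    if not de_genes:
        logger.warning("empty DE set: no enrichment computed")
        return pd.DataFrame(
            columns=["category", "k", "n", "K", "N", "fold_enrichment", "p", "q"]
        )
    n = len(de_genes)
    N = len(background)
    rows = []
    ann = annotation[annotation["gene_id"].isin(background)]
    for category, sub in ann.groupby("category", sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & de_genes)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        _, p = sps.fisher_exact(table, alternative="two-sided")
        fold = (k / n) / (K / N)
        rows.append(
            {"category": category, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bin_conservation(values, n_bins: int = 10) -> np.ndarray:
    """Histogram of conservation fractions over equal-width bins on [0, 1].

    Bins are left-inclusive; the last bin is right-inclusive, so counts
    always sum to the number of input values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
        raise InvalidInputError("conservation values must lie in [0, 1]")
    counts, _ = np.histogram(arr, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return counts


def call_expression(
    table: pd.DataFrame,
    fold: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run zeroing, DE calling and salinity classification in one pass.

    Returns a DataFrame indexed by gene_id with the zeroed lfcs, ``is_de``
    and ``salt_class``.
    """
    zeroed = zero_nonsignificant(table, alpha=alpha)
    de_flags = call_differential_genes(zeroed, fold=fold)
    salt = call_salinity_responsive(zeroed, de_flags, fold=fold)
    out = zeroed.copy()
    out.columns = [f"{c}_lfc0" for c in zeroed.columns]
    out["is_de"] = de_flags
    out["salt_class"] = salt
    n_up = int((salt == "salt_up").sum())
    n_down = int((salt == "salt_down").sum())
    logger.info("DE genes: %d (salt_up %d, salt_down %d)", int(de_flags.sum()), n_up, n_down)
    return out
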