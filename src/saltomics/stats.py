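"""Vectorised ANOVA machinery and FDR adjustment.

The differential-feature workflow runs the same classical tests over
thousands of LC-MS features at once, so the one-way and balanced two-way
ANOVA are implemented as closed-form sum-of-squares decompositions on a
``(n_features, n_observations)`` array rather than per-feature model fits.
For a balanced design the type I/II/III decompositions coincide, so the
plain partition

    SS_total = SS_A + SS_B + SS_AB + SS_error

is exact and each term's F statistic is its mean square over the error
mean square.

Degenerate features are handled by fixed conventions rather than NaN
propagation:

* zero total variance (all observations identical): the test is
  uninformative, ``p = 1`` and the feature is flagged degenerate;
* zero within-group variance with non-zero between-group variance
  (perfect separation): ``F = inf`` and ``p`` is floored at ``P_FLOOR``
  so that log-scale reporting stays finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidDesignError, InvalidInputError

#: Smallest reported p-value for perfectly separated groups.
P_FLOOR = 1e-300


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise InvalidInputError("values must be 1- or 2-dimensional")
    return arr


def one_way_anova(values, groups) -> pd.DataFrame:
    """Classical one-way ANOVA, vectorised over rows of ``values``.

    Parameters
    ----------
    values
        ``(n_features, n_obs)`` array (log10-transformed signals in the
        metabolomics workflow).
    groups
        Length ``n_obs`` group labels; every group needs >= 2 observations.

    Returns
    -------
    DataFrame with columns ``F``, ``p`` and boolean ``degenerate``.
    """
    arr = _as_2d(values)
    groups = np.asarray(groups)
    if groups.size != arr.shape[1]:
        raise InvalidInputError("group labels do not match observations")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise InvalidDesignError("one-way ANOVA needs >= 2 groups")
    if counts.min() < 2:
        raise InvalidDesignError("every group needs >= 2 observations")

    grand = arr.mean(axis=1)
    ss_between = np.zeros(arr.shape[0])
    ss_within = np.zeros(arr.shape[0])
    for g, n_g in zip(uniq, counts):
        block = arr[:, groups == g]
        m = block.mean(axis=1)
        ss_between += n_g * (m - grand) ** 2
        ss_within += ((block - m[:, None]) ** 2).sum(axis=1)

    df1 = uniq.size - 1
    df2 = groups.size - uniq.size
    degenerate = (ss_between + ss_within) == 0.0
    separated = (ss_within == 0.0) & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df1) / (ss_within / df2)
    p = np.where(np.isfinite(f_stat), sps.f.sf(np.where(np.isfinite(f_stat), f_stat, 0.0), df1, df2), np.nan)
    p = np.maximum(p, P_FLOOR)
    p[separated] = P_FLOOR
    f_stat[separated] = np.inf
    p[degenerate] = 1.0
    f_stat[degenerate] = np.nan
    return pd.DataFrame({"F": f_stat, "p": p, "degenerate": degenerate})


def levene_test(values, groups) -> pd.DataFrame:
    """Brown-Forsythe test for equality of group variances, vectorised.

    Absolute deviations from the group *median* are computed per feature,
    then fed through :func:`one_way_anova`; this is the median-centred
    (robust) Levene variant. Reported for audit, never used as a filter.
    """
    arr = _as_2d(values)
    groups = np.asarray(groups)
    dev = np.empty_like(arr)
    for g in np.unique(groups):
        mask = groups == g
        med = np.median(arr[:, mask], axis=1)
        dev[:, mask] = np.abs(arr[:, mask] - med[:, None])
    out = one_way_anova(dev, groups)
    return out.rename(columns={"F": "W"})


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Balanced full-factorial two-way ANOVA, vectorised over rows.

    ``factor_a`` is the salinity condition (2 levels) and ``factor_b`` the
    time point (3 levels) in the metabolomics workflow, but any complete
    balanced a x b design with r >= 2 replicates per cell is accepted.

    Returns a DataFrame with per-term F and p (``F_a``, ``p_a``, ``F_b``,
    ``p_b``, ``F_ab``, ``p_ab``), the sums of squares (``ss_a``, ``ss_b``,
    ``ss_ab``, ``ss_err``, ``ss_total``) and a ``degenerate`` flag.
    """
    arr = _as_2d(values)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if fa.size != arr.shape[1] or fb.size != arr.shape[1]:
        raise InvalidInputError("factor labels do not match observations")
    levels_a = np.unique(fa)
    levels_b = np.unique(fb)
    a, b = levels_a.size, levels_b.size
    cell_counts = {
        (la, lb): int(((fa == la) & (fb == lb)).sum())
        for la in levels_a
        for lb in levels_b
    }
    r = next(iter(cell_counts.values()))
    if r < 2 or any(c != r for c in cell_counts.values()):
        raise InvalidDesignError(
            "two-way ANOVA requires a complete balanced design with >= 2 replicates per cell"
        )

    n_feat = arr.shape[0]
    grand = arr.mean(axis=1)
    cell_means = np.empty((n_feat, a, b))
    for i, la in enumerate(levels_a):
        for j, lb in enumerate(levels_b):
            cell = arr[:, (fa == la) & (fb == lb)]
            cell_means[:, i, j] = cell.mean(axis=1)
    mean_a = cell_means.mean(axis=2)  # (n_feat, a)
    mean_b = cell_means.mean(axis=1)  # (n_feat, b)

    ss_a = b * r * ((mean_a - grand[:, None]) ** 2).sum(axis=1)
    ss_b = a * r * ((mean_b - grand[:, None]) ** 2).sum(axis=1)
    inter = (
        cell_means
        - mean_a[:, :, None]
        - mean_b[:, None, :]
        + grand[:, None, None]
    )
    ss_ab = r * (inter**2).sum(axis=(1, 2))
    ss_err = np.zeros(n_feat)
    for i, la in enumerate(levels_a):
        for j, lb in enumerate(levels_b):
            cell = arr[:, (fa == la) & (fb == lb)]
            ss_err += ((cell - cell_means[:, i, j][:, None]) ** 2).sum(axis=1)
    ss_total = ss_a + ss_b + ss_ab + ss_err

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (r - 1)
    degenerate = ss_total == 0.0

    out = {}
    for term, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("ab", ss_ab, df_ab)):
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = (ss / df) / (ss_err / df_err)
        separated = (ss_err == 0.0) & (ss > 0.0)
        null_term = (ss_err == 0.0) & (ss == 0.0)
        p = np.where(
            np.isfinite(f_stat),
            sps.f.sf(np.where(np.isfinite(f_stat), f_stat, 0.0), df, df_err),
            np.nan,
        )
        p = np.maximum(p, P_FLOOR)
        p[separated] = P_FLOOR
        f_stat[separated] = np.inf
        p[null_term] = 1.0
        f_stat[null_term] = np.nan
        out[f"F_{term}"] = f_stat
        out[f"p_{term}"] = p
    out.update(
        ss_a=ss_a, ss_b=ss_b, ss_ab=ss_ab, ss_err=ss_err, ss_total=ss_total,
        degenerate=degenerate,
    )
    return pd.DataFrame(out)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns monotone q-values (q >= p, order-preserving); raises
    :class:`InvalidInputError` on p outside [0, 1]. Empty input yields an
    empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
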