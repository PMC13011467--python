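"""Staged differential-abundance calling for untargeted LC-MS feature tables.

The workflow screens a feature x sample signal matrix from a two-salinity,
three-time-point, triplicate culture experiment for features significantly
over- or under-produced between salinity conditions over time. Stages run
in a fixed order, each one narrowing the feature set:

1.  blank filter    — drop features not >= 3x more abundant than blanks;
2.  retention time  — keep 0.5 min <= RT <= 8 min;
3.  signal floor    — drop features below 1e7 in every biological sample;
4.  pseudocount     — add 1e4 to every signal (once);
5.  10x prefilter   — keep features whose six condition x time group means
                      span at least a 10-fold ratio;
6.  one-way ANOVA   — on log10 signals over the six groups, BH-FDR < 0.05;
                      Levene (Brown-Forsythe) variance homogeneity is
                      recorded alongside, never filtered on;
7.  two-way ANOVA   — salinity x time with interaction; interaction-term
                      BH-FDR < 0.05;
8.  100x gate       — group-mean span >= 100-fold.

A feature is called differential only if it survives every stage. FDR
adjustment at each testing stage is computed only across the features that
reached that stage, and positive- and negative-ionisation-mode features
are analysed as separate tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidConfigError,
    InvalidDesignError,
    InvalidInputError,
    PipelineStateError,
)
from .stats import bh_adjust, levene_test, one_way_anova, two_way_anova

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("mz", "rt", "mode")
SAMPLE_COLUMNS = ("condition", "time_h", "replicate", "is_blank")


@dataclass
class Thresholds:
    """Numeric gates of the differential-feature workflow.

    Defaults are the study values: signals below ``signal_floor`` in every
    biological sample are noise; ``pseudocount`` regularises ratios and
    logs; ``prefilter_fold`` and ``interaction_fold`` are the 10x screen
    and the final 100x effect-size gate on the span of the six condition x
    time group means; ``fdr_alpha`` applies to both BH-adjusted ANOVA
    stages; ``blank_ratio`` and the retention-time window reproduce the
    upstream feature-list filters.
    """

    signal_floor: float = 1e7
    pseudocount: float = 1e4
    prefilter_fold: float = 10.0
    fdr_alpha: float = 0.05
    interaction_fold: float = 100.0
    blank_ratio: float = 3.0
    rt_min: float = 0.5
    rt_max: float = 8.0

    def __post_init__(self):
        vals = (
            self.signal_floor, self.pseudocount, self.prefilter_fold,
            self.fdr_alpha, self.interaction_fold, self.blank_ratio,
            self.rt_min, self.rt_max,
        )
        if any(v <= 0 for v in vals):
            raise InvalidConfigError("all thresholds must be positive")
        if self.rt_min >= self.rt_max:
            raise InvalidConfigError("rt_min must be < rt_max")


@dataclass
class FeatureTable:
    """LC-MS feature x sample signal matrix with its sample design.

    ``features``: per-feature metadata indexed by feature_id with columns
    ``mz`` (Da), ``rt`` (min), ``mode`` ({positive, negative}).
    ``signals``: features x samples non-negative signal matrix.
    ``samples``: per-sample design indexed by sample_id with columns
    ``condition``, ``time_h``, ``replicate``, ``is_blank``.
    """

    features: pd.DataFrame
    signals: pd.DataFrame
    samples: pd.DataFrame
    pseudocount_applied: bool = field(default=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.features.index.is_unique:
            raise InvalidInputError("feature_ids must be unique")
        if not self.features.index.equals(self.signals.index):
            raise InvalidInputError("features and signals must share the same index")
        if list(self.signals.columns) != list(self.samples.index):
            raise InvalidInputError("signal columns must match sample metadata")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InvalidInputError(f"sample metadata missing columns: {missing}")
        if (self.signals.to_numpy() < 0).any():
            raise InvalidInputError("signals must be non-negative")

    @property
    def nonblank_samples(self) -> pd.Index:
        return self.samples.index[~self.samples["is_blank"].astype(bool)]

    @property
    def blank_samples(self) -> pd.Index:
        return self.samples.index[self.samples["is_blank"].astype(bool)]

    def group_labels(self) -> pd.Series:
        """Condition x time group label per non-blank sample."""
        meta = self.samples.loc[self.nonblank_samples]
        return meta["condition"].astype(str) + "@" + meta["time_h"].astype(str)

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            features=self.features.loc[feature_ids],
            signals=self.signals.loc[feature_ids],
            samples=self.samples,
            pseudocount_applied=self.pseudocount_applied,
        )

    def check_balanced(self, n_replicates: int = 3) -> None:
        meta = self.samples.loc[self.nonblank_samples]
        counts = meta.groupby(["condition", "time_h"], sort=True).size()
        if counts.empty or (counts != n_replicates).any():
            raise InvalidDesignError(
                f"non-blank design is not a complete factorial with {n_replicates} replicates"
            )


# ---------------------------------------------------------------------------
# individual stages


def filter_blank(table: FeatureTable, thresholds: Thresholds) -> FeatureTable:
    """Keep features whose max biological signal >= blank_ratio x max blank signal."""
    blanks = table.blank_samples
    if len(blanks) == 0:
        raise InvalidConfigError("blank filtering requires >= 1 blank sample")
    max_bio = table.signals[table.nonblank_samples].max(axis=1)
    max_blank = table.signals[blanks].max(axis=1)
    keep = max_bio >= thresholds.blank_ratio * max_blank
    return table.subset(table.features.index[keep])


def filter_retention_time(table: FeatureTable, thresholds: Thresholds) -> FeatureTable:
    """Keep features with rt_min <= RT <= rt_max (both inclusive)."""
    rt = table.features["rt"]
    if rt.isna().any():
        raise InvalidInputError("retention time missing for some features")
    keep = (rt >= thresholds.rt_min) & (rt <= thresholds.rt_max)
    return table.subset(table.features.index[keep])


def filter_low_signal(table: FeatureTable, thresholds: Thresholds) -> FeatureTable:
    """Drop features below the signal floor in *every* biological sample."""
    keep = table.signals[table.nonblank_samples].max(axis=1) >= thresholds.signal_floor
    return table.subset(table.features.index[keep])


def add_pseudocount(table: FeatureTable, thresholds: Thresholds) -> FeatureTable:
    """Add the pseudocount to every signal; refuses to run twice."""
    if table.pseudocount_applied:
        raise PipelineStateError("pseudocount already applied")
    return FeatureTable(
        features=table.features,
        signals=table.signals + thresholds.pseudocount,
        samples=table.samples,
        pseudocount_applied=True,
    )


def group_means(table: FeatureTable) -> pd.DataFrame:
    """Arithmetic replicate mean per condition x time group, per feature."""
    if not table.pseudocount_applied:
        raise PipelineStateError("group means are computed on pseudocounted signals")
    table.check_balanced()
    labels = table.group_labels()
    sig = table.signals[table.nonblank_samples]
    return sig.T.groupby(labels).mean().T


def _fold_span(means: pd.DataFrame) -> pd.Series:
    return means.max(axis=1) / means.min(axis=1)


def prefilter_fold_change(means: pd.DataFrame, thresholds: Thresholds) -> pd.Series:
    """True where max/min over the six group means >= prefilter_fold."""
    return _fold_span(means) >= thresholds.prefilter_fold


def interaction_fold_gate(means: pd.DataFrame, thresholds: Thresholds) -> pd.Series:
    """True where max/min over the six group means >= interaction_fold."""
    return _fold_span(means) >= thresholds.interaction_fold


# ---------------------------------------------------------------------------
# full workflow


def _call_single_mode(table: FeatureTable, thresholds: Thresholds):
    index = table.features.index
    res = pd.DataFrame(index=index)
    for col in ("blank_pass", "rt_pass", "floor_pass", "prefilter_pass",
                "oneway_pass", "interaction_pass", "fold_pass", "final_call",
                "degenerate"):
        res[col] = False
    for col in ("F1", "p1", "q1", "levene_W", "levene_p",
                "p_sal", "p_time", "p_int", "q_sal", "q_time", "q_int",
                "max_fold"):
        res[col] = np.nan

    audit = []

    def record(stage: str, before: pd.Index, after: pd.Index):
        audit.append({"stage": stage, "n_in": len(before), "n_out": len(after)})
        logger.info("%s: %d -> %d features", stage, len(before), len(after))

    t = filter_blank(table, thresholds)
    res.loc[t.features.index, "blank_pass"] = True
    record("blank", index, t.features.index)

    prev = t.features.index
    t = filter_retention_time(t, thresholds)
    res.loc[t.features.index, "rt_pass"] = True
    record("retention_time", prev, t.features.index)

    prev = t.features.index
    t = filter_low_signal(t, thresholds)
    res.loc[t.features.index, "floor_pass"] = True
    record("signal_floor", prev, t.features.index)

    t = add_pseudocount(t, thresholds)
    means = group_means(t)
    res.loc[means.index, "max_fold"] = _fold_span(means)

    prev = t.features.index
    pre_ok = prefilter_fold_change(means, thresholds)
    t = t.subset(t.features.index[pre_ok])
    res.loc[t.features.index, "prefilter_pass"] = True
    record("prefilter_10x", prev, t.features.index)

    if len(t.features.index):
        labels = t.group_labels().to_numpy()
        values = np.log10(t.signals[t.nonblank_samples].to_numpy())
        ow = one_way_anova(values, labels)
        ow.index = t.features.index
        res.loc[ow.index, ["F1", "p1"]] = ow[["F", "p"]].to_numpy()
        res.loc[ow.index, "degenerate"] = ow["degenerate"].to_numpy()
        res.loc[ow.index, "q1"] = bh_adjust(ow["p"].to_numpy())

        lev = levene_test(values, labels)
        lev.index = t.features.index
        res.loc[lev.index, ["levene_W", "levene_p"]] = lev[["W", "p"]].to_numpy()

        prev = t.features.index
        ow_ok = res.loc[t.features.index, "q1"] < thresholds.fdr_alpha
        t = t.subset(t.features.index[ow_ok])
        res.loc[t.features.index, "oneway_pass"] = True
        record("oneway_fdr", prev, t.features.index)
    else:
        record("oneway_fdr", t.features.index, t.features.index)

    if len(t.features.index):
        meta = t.samples.loc[t.nonblank_samples]
        values = np.log10(t.signals[t.nonblank_samples].to_numpy())
        tw = two_way_anova(values, meta["condition"].to_numpy(), meta["time_h"].to_numpy())
        tw.index = t.features.index
        res.loc[tw.index, ["p_sal", "p_time", "p_int"]] = (
            tw[["p_a", "p_b", "p_ab"]].to_numpy()
        )
        for term, src in (("q_sal", "p_a"), ("q_time", "p_b"), ("q_int", "p_ab")):
            res.loc[tw.index, term] = bh_adjust(tw[src].to_numpy())

        prev = t.features.index
        int_ok = res.loc[t.features.index, "q_int"] < thresholds.fdr_alpha
        t = t.subset(t.features.index[int_ok])
        res.loc[t.features.index, "interaction_pass"] = True
        record("interaction_fdr", prev, t.features.index)
    else:
        record("interaction_fdr", t.features.index, t.features.index)

    prev = t.features.index
    gate = interaction_fold_gate(means.loc[t.features.index], thresholds)
    t = t.subset(t.features.index[gate])
    res.loc[t.features.index, "fold_pass"] = True
    res.loc[t.features.index, "final_call"] = True
    record("fold_gate_100x", prev, t.features.index)

    return res, pd.DataFrame(audit)


def call_differential_features(
    table: FeatureTable,
    thresholds: Thresholds | None = None,
    per_mode: bool = True,
):
    """Run the full staged workflow; returns ``(results, audit)``.

    ``results`` has one row per input feature with every stage flag, test
    statistic and the final call; ``audit`` records per-stage in/out
    counts. With ``per_mode=True`` (default) positive- and
    negative-ionisation features are processed as independent tables, so
    FDR adjustment never pools across modes.
    """
    thresholds = thresholds or Thresholds()
    if per_mode and "mode" in table.features.columns:
        parts, audits = [], []
        for mode, ids in table.features.groupby("mode", sort=True).groups.items():
            res, audit = _call_single_mode(table.subset(ids), thresholds)
            res.insert(0, "mode", mode)
            audit.insert(0, "mode", mode)
            parts.append(res)
            audits.append(audit)
        results = pd.concat(parts).loc[table.features.index]
        return results, pd.concat(audits, ignore_index=True)
    return _call_single_mode(table, thresholds)
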