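"""Fold changes, significance and senolytic classification from well counts.

The assay's decision rule: a compound is *senolytic* when it significantly
reduces the senescent (RFP) nucleus count relative to vehicle while leaving
the quiescent (GFP) count unaffected.  Counts are summarized per condition
and channel as fold change to the vehicle mean, compared with an unpaired
two-tailed pooled-variance Student's t-test, and classified into
``senolytic | toxic | quiescent-selective | inert``.

The independent replicate unit is the well: fields imaged within a well are
summed before statistics.  No multiple-testing correction is applied by
default (per-comparison tests are the norm for small validation panels);
Benjamini–Hochberg is available for screening-scale use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientReplicationError,
    SchemaError,
    UndefinedBaselineError,
)

logger = logging.getLogger("senolytica.senolysis")

__all__ = [
    "validate_assay_table",
    "fold_change",
    "significance",
    "classify",
    "score",
    "SenolysisResult",
]

_REQUIRED = ("well_id", "condition", "replicate", "channel", "count")


def validate_assay_table(table: pd.DataFrame, vehicle: str) -> pd.DataFrame:
    """Check the long-format assay table contract and return it unchanged.

    Columns ``well_id, condition, replicate, channel, count``; counts must
    be non-negative integers and the vehicle condition must be present with
    at least two replicate wells.
    """
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"assay table missing column(s) {missing}")
    counts = table["count"]
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if vehicle not in set(table["condition"]):
        raise ValueError(f"vehicle condition {vehicle!r} not present")
    n_vehicle = table.loc[table["condition"] == vehicle, "well_id"].nunique()
    if n_vehicle < 2:
        raise InsufficientReplicationError(
            f"vehicle {vehicle!r} has {n_vehicle} replicate well(s); need >= 2"
        )
    return table


def _well_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Sum fields within a well: one row per (condition, channel, well)."""
    return (
        table.groupby(["condition", "channel", "well_id"], as_index=False)["count"]
        .sum()
    )


def fold_change(table: pd.DataFrame, vehicle: str) -> pd.DataFrame:
    """Per-(condition, channel) fold change to the vehicle mean.

    ``fold_change = mean(condition counts) / mean(vehicle counts)`` per
    channel; ``sd`` is the SD of the condition's replicate counts divided by
    the vehicle mean (replicates normalized to baseline).  The vehicle rows
    have fold change exactly 1.  A zero vehicle mean for a channel raises
    :class:`UndefinedBaselineError`.
    """
    validate_assay_table(table, vehicle)
    wells = _well_counts(table)
    rows = []
    for channel, chan_wells in wells.groupby("channel"):
        veh = chan_wells.loc[chan_wells["condition"] == vehicle, "count"]
        veh_mean = float(veh.mean())
        if veh_mean == 0:
            raise UndefinedBaselineError(
                f"vehicle mean count is 0 for channel {channel!r}; fold change undefined"
            )
        for condition, grp in chan_wells.groupby("condition"):
            counts = grp["count"].to_numpy(dtype=float)
            rows.append(
                {
                    "condition": condition,
                    "channel": channel,
                    "n": len(counts),
                    "mean": float(counts.mean()),
                    "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                    "fold_change": float(counts.mean()) / veh_mean,
                    "fold_change_sd": (
                        float(counts.std(ddof=1)) / veh_mean if len(counts) > 1 else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


def _pooled_t_pvalue(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError(
            f"t-test needs >= 2 replicates per group (got {len(a)} vs {len(b)})"
        )
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("zero variance in both groups with equal means; p = 1 by convention")
            return 1.0
        return 0.0  # identical replicates, different means: maximal evidence
    result = stats.ttest_ind(a, b, equal_var=not welch)
    return float(result.pvalue)


def significance(
    table: pd.DataFrame, vehicle: str, welch: bool = False
) -> pd.DataFrame:
    """Two-tailed Student's t-test of each condition against the vehicle.

    Pooled-variance by default (the classical Student's test); pass
    ``welch=True`` for the unequal-variance variant.  Identical
    zero-variance groups get p = 1 by convention.
    """
    validate_assay_table(table, vehicle)
    wells = _well_counts(table)
    rows = []
    for channel, chan_wells in wells.groupby("channel"):
        veh = chan_wells.loc[chan_wells["condition"] == vehicle, "count"] \
            .to_numpy(dtype=float)
        for condition, grp in chan_wells.groupby("condition"):
            counts = grp["count"].to_numpy(dtype=float)
            p = 1.0 if condition == vehicle else _pooled_t_pvalue(counts, veh, welch)
            rows.append({"condition": condition, "channel": channel, "p_value": p})
    return pd.DataFrame(rows)


def classify(
    stats_table: pd.DataFrame,
    alpha: float = 0.05,
    quiescent_drop_limit: float = 0.2,
    gfp_channel: str = "GFP",
    rfp_channel: str = "RFP",
) -> pd.Series:
    """Verdict per condition from fold changes and p-values.

    * ``senolytic`` — RFP fold change < 1 with p < alpha while GFP is
      unaffected (p ≥ alpha, or fold change ≥ 1 − ``quiescent_drop_limit``);
    * ``toxic`` — both channels significantly reduced beyond the drop limit;
    * ``quiescent-selective`` — only GFP significantly reduced beyond it;
    * ``inert`` — anything else.

    "Unaffected" needs an operational tolerance; ``quiescent_drop_limit``
    (default 20%) is that tolerance and is deliberately exposed.
    """
    verdicts = {}
    for condition, grp in stats_table.groupby("condition"):
        by_chan = grp.set_index("channel")
        try:
            rfp = by_chan.loc[rfp_channel]
            gfp = by_chan.loc[gfp_channel]
        except KeyError as exc:
            raise SchemaError(f"condition {condition!r} missing channel {exc}") from exc
        floor = 1.0 - quiescent_drop_limit
        rfp_hit = rfp["fold_change"] < 1.0 and rfp["p_value"] < alpha
        rfp_deep = rfp["fold_change"] < floor and rfp["p_value"] < alpha
        gfp_deep = gfp["fold_change"] < floor and gfp["p_value"] < alpha
        gfp_ok = gfp["p_value"] >= alpha or gfp["fold_change"] >= floor
        if rfp_deep and gfp_deep:
            verdicts[condition] = "toxic"
        elif rfp_hit and gfp_ok:
            verdicts[condition] = "senolytic"
        elif gfp_deep and not rfp_hit:
            verdicts[condition] = "quiescent-selective"
        else:
            verdicts[condition] = "inert"
    return pd.Series(verdicts, name="verdict")


@dataclass
class SenolysisResult:
    """Per-(condition, channel) statistics plus per-condition verdicts."""

    stats: pd.DataFrame
    verdicts: pd.Series

    def table(self) -> pd.DataFrame:
        out = self.stats.copy()
        out["verdict"] = out["condition"].map(self.verdicts)
        return out


def score(
    table: pd.DataFrame,
    vehicle: str,
    alpha: float = 0.05,
    quiescent_drop_limit: float = 0.2,
    welch: bool = False,
    bh_correct: bool = False,
) -> SenolysisResult:
    """Full scoring pipeline: fold changes + t-tests + classification.

    With ``bh_correct=True``, Benjamini–Hochberg adjusts the non-vehicle
    p-values across all (condition, channel) comparisons before
    classification — useful when scoring whole screening plates.
    """
    fc = fold_change(table, vehicle)
    pv = significance(table, vehicle, welch=welch)
    merged = fc.merge(pv, on=["condition", "channel"])
    if bh_correct:
        mask = merged["condition"] != vehicle
        pvals = merged.loc[mask, "p_value"].to_numpy()
        if len(pvals):
            merged.loc[mask, "p_value"] = stats.false_discovery_control(pvals)
    verdicts = classify(
        merged[merged["condition"] != vehicle],
        alpha=alpha,
        quiescent_drop_limit=quiescent_drop_limit,
    )
    verdicts[vehicle] = "vehicle"
    return SenolysisResult(stats=merged, verdicts=verdicts)
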