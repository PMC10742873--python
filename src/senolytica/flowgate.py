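"""Quadrant gating of isolated-nuclei flow-cytometry events.

The orthogonal validation of the imaging assay: nuclei isolated from the
co-culture are stained with DAPI and run through a cytometer, and the
GFP⁺/RFP⁺ population frequencies are compared between vehicle and treated
samples.  Events are first gated on DAPI (intact nuclei), then assigned to
one of four quadrants by one threshold per fluorophore channel.

Frequencies are compositional — killing RFP⁺ nuclei inflates the GFP⁺
*fraction* even at constant GFP⁺ *count* — so absolute per-population
counts are reported alongside the fractions.

Input is a CSV-derived event table, not FCS binaries (conversion is
upstream).  Automatic thresholding works on log10(1 + x), where flow
intensities are approximately normal per population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import EmptyInputError
from .senolysis import _pooled_t_pvalue

logger = logging.getLogger("senolytica.flowgate")

__all__ = ["GateSpec", "GateResult", "auto_threshold", "gate_events", "compare_conditions"]

POPULATIONS = ("gfp_pos", "rfp_pos", "double_pos", "double_neg")


@dataclass
class GateSpec:
    """DAPI gate plus quadrant thresholds.

    ``threshold_mode="auto"`` places each fluorophore threshold at the
    minimum of a smoothed log-intensity histogram between its two largest
    modes; unimodal channels fall back to the fixed threshold with a
    warning.
    """

    dapi_min: float = 100.0
    gfp_threshold: float = 1000.0
    rfp_threshold: float = 1000.0
    threshold_mode: str = "fixed"  # "fixed" | "auto"

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "auto"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.gfp_threshold <= 0 or self.rfp_threshold <= 0:
                raise ValueError("fixed thresholds must be positive")


@dataclass
class GateResult:
    """Quadrant frequencies (fractions of intact events) and counts."""

    n_total: int
    n_intact: int
    frequencies: dict[str, float]
    counts: dict[str, int]
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_intact > 0:
            total = sum(self.frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"quadrant frequencies sum to {total}, not 1")


def auto_threshold(values: np.ndarray, bins: int = 256, smooth_sigma: float = 3.0) -> float | None:
    """Valley threshold between the two largest modes of log10(1 + x).

    Returns the threshold on the original intensity scale, or ``None``
    when the smoothed histogram is unimodal.
    """
    logv = np.log10(1.0 + np.asarray(values, dtype=float))
    hist, edges = np.histogram(logv, bins=bins)
    smoothed = gaussian_filter1d(hist.astype(float), smooth_sigma)
    # genuine positive/negative modes sit at least ~half a decade apart;
    # closer bumps are shot noise on a single population
    bin_width = edges[1] - edges[0]
    min_mode_separation_bins = max(1, int(0.5 / bin_width))
    peaks, _ = find_peaks(
        smoothed,
        prominence=0.05 * smoothed.max(),
        distance=min_mode_separation_bins,
    )
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(smoothed[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(smoothed[lo : hi + 1]))
    log_thr = 0.5 * (edges[valley] + edges[valley + 1])
    return float(10.0**log_thr - 1.0)


def gate_events(events: pd.DataFrame, spec: GateSpec | None = None) -> GateResult:
    """Gate an event table into the four GFP/RFP quadrants.

    Events with ``dapi >= dapi_min`` are intact nuclei; frequencies are
    fractions of intact events and always sum to 1 when any intact event
    exists.  If every event fails the DAPI gate the result reports all-zero
    frequencies with a warning.
    """
    spec = spec or GateSpec()
    if events.empty:
        raise EmptyInputError("event table is empty")
    intact = events[events["dapi"] >= spec.dapi_min]
    n_total, n_intact = len(events), len(intact)
    if n_intact == 0:
        logger.warning("no events pass the DAPI gate (dapi_min=%g)", spec.dapi_min)
        return GateResult(
            n_total=n_total, n_intact=0,
            frequencies={p: 0.0 for p in POPULATIONS},
            counts={p: 0 for p in POPULATIONS},
            thresholds={"gfp": spec.gfp_threshold, "rfp": spec.rfp_threshold,
                        "dapi_min": spec.dapi_min},
        )

    thr = {"gfp": spec.gfp_threshold, "rfp": spec.rfp_threshold}
    if spec.threshold_mode == "auto":
        for chan in ("gfp", "rfp"):
            auto = auto_threshold(intact[chan].to_numpy())
            if auto is None:
                logger.warning(
                    "auto threshold: channel %s is unimodal; falling back to fixed %g",
                    chan, thr[chan],
                )
            else:
                thr[chan] = auto

    gfp_hi = intact["gfp"].to_numpy() > thr["gfp"]
    rfp_hi = intact["rfp"].to_numpy() > thr["rfp"]
    counts = {
        "gfp_pos": int(np.sum(gfp_hi & ~rfp_hi)),
        "rfp_pos": int(np.sum(~gfp_hi & rfp_hi)),
        "double_pos": int(np.sum(gfp_hi & rfp_hi)),
        "double_neg": int(np.sum(~gfp_hi & ~rfp_hi)),
    }
    frequencies = {p: counts[p] / n_intact for p in POPULATIONS}
    return GateResult(
        n_total=n_total,
        n_intact=n_intact,
        frequencies=frequencies,
        counts=counts,
        thresholds={**thr, "dapi_min": spec.dapi_min},
    )


def compare_conditions(
    results: dict[str, list[GateResult]],
    vehicle: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Frequency fold changes and t-tests of each condition against vehicle.

    ``results`` maps condition → replicate :class:`GateResult` list.  For
    each population the table reports the fold change of the mean frequency
    (and of the mean absolute count) versus vehicle, plus a two-tailed
    pooled-variance Student's t-test over replicate frequencies.
    """
    if vehicle not in results:
        raise ValueError(f"vehicle condition {vehicle!r} not in results")
    veh_freq = {
        p: np.array([r.frequencies[p] for r in results[vehicle]]) for p in POPULATIONS
    }
    veh_count = {
        p: np.array([float(r.counts[p]) for r in results[vehicle]]) for p in POPULATIONS
    }
    rows = []
    for condition, reps in results.items():
        for pop in POPULATIONS:
            freqs = np.array([r.frequencies[pop] for r in reps])
            counts = np.array([float(r.counts[pop]) for r in reps])
            veh_mean = veh_freq[pop].mean()
            veh_count_mean = veh_count[pop].mean()
            if condition == vehicle:
                p_value = 1.0
            else:
                p_value = _pooled_t_pvalue(freqs, veh_freq[pop])

            def _fc(mean: float, veh: float) -> float:
                # an empty population in both groups is unchanged; an empty
                # vehicle baseline with a populated condition is undefined
                if veh > 0:
                    return float(mean / veh)
                return 1.0 if mean == 0 else np.nan

            rows.append(
                {
                    "condition": condition,
                    "population": pop,
                    "n": len(reps),
                    "mean_frequency": float(freqs.mean()),
                    "sd_frequency": float(freqs.std(ddof=1)) if len(freqs) > 1 else 0.0,
                    "frequency_fold_change": _fc(freqs.mean(), veh_mean),
                    "count_fold_change": _fc(counts.mean(), veh_count_mean),
                    "p_value": p_value,
                    "significant": p_value < alpha and condition != vehicle,
                }
            )
    return pd.DataFrame(rows)
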