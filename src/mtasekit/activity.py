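"""Coupled-assay methyltransferase activity quantification.

The methyl-transfer product (s-adenosylhomocysteine) is quantified through
an enzymatic cascade that produces fluorescent resorufin; the initial slope
of the resorufin trace is proportional to the product concentration.  Rates
are normalised to the enzyme concentration, then expressed relative to a
wild-type and a knock-out control:

    ratio = (median(variant) − median(ko)) / (median(wt) − median(ko)).

A variant is flagged below the detection limit when its median rate does not
exceed the knock-out median by more than k·IQR of the knock-out replicates
(k = 1 by default) — the knock-out signal defines the assay floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats


@dataclass
class KineticTrace:
    """Fluorometric trace of resorufin production for one reaction."""

    times: np.ndarray          # minutes
    intensities: np.ndarray    # arbitrary units
    sample: str = ""
    protein_concentration: float | None = None  # µM, from A280 (ε = 44,810 /M/cm)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("time/intensity arrays differ in length")
        if self.times.size < 5:
            raise ValueError("trace needs at least 5 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class RateResult:
    initial_rate: float                 # a.u./min
    normalised_rate: float | None       # a.u./min/µM (None without concentration)
    window: tuple[float, float]
    n_points: int
    r_squared: float
    linear_window_found: bool = True


@dataclass
class ActivityRatio:
    ratio_to_wt: float
    median_rate: float
    iqr: float
    n_replicates: int
    below_detection: bool
    ratio_no_subtraction: float
    median_of_ratios: float


def _ols_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def initial_rate(
    trace: KineticTrace,
    min_points: int = 5,
    r2_threshold: float = 0.98,
    saturation_fraction: float = 0.2,
) -> RateResult:
    """Initial slope over the longest linear early window of the trace.

    Trailing saturation is trimmed first: the tail where the local
    ``min_points``-point slope drops below ``saturation_fraction`` of the
    steepest local slope is excluded.  Within the remaining rise, the window
    grows from the start of the trace and the longest prefix of at least
    ``min_points`` with OLS R² ≥ ``r2_threshold`` is used.  If no prefix
    qualifies, the first ``min_points`` points are used with a warning.
    When the trace carries a protein concentration the rate is additionally
    reported per µM of enzyme.
    """
    t, y = trace.times, trace.intensities
    end_max = len(t)
    if end_max > min_points:
        local = np.array(
            [
                _ols_r2(t[i : i + min_points], y[i : i + min_points])[0]
                for i in range(end_max - min_points + 1)
            ]
        )
        smax = local.max()
        if smax > 0:
            # first local window dominated by plateau marks the cut
            falling = np.nonzero(local < saturation_fraction * smax)[0]
            if falling.size:
                end_max = max(min_points, int(falling.min()))
    best = None
    for end in range(min_points, end_max + 1):
        slope, _, r2 = _ols_r2(t[:end], y[:end])
        if r2 >= r2_threshold:
            best = (end, slope, r2)
    if best is None:
        warnings.warn(
            f"no window with R² >= {r2_threshold} in trace {trace.sample!r}; "
            f"falling back to first {min_points} points"
        )
        slope, _, r2 = _ols_r2(t[:min_points], y[:min_points])
        end = min_points
        found = False
    else:
        end, slope, r2 = best
        found = True
    norm = (
        slope / trace.protein_concentration
        if trace.protein_concentration
        else None
    )
    return RateResult(
        initial_rate=slope,
        normalised_rate=norm,
        window=(float(t[0]), float(t[end - 1])),
        n_points=end,
        r_squared=r2,
        linear_window_found=found,
    )


def _iqr(x: np.ndarray) -> float:
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def activity_ratio(
    variant_rates: Sequence[float],
    wt_rates: Sequence[float],
    ko_rates: Sequence[float],
    detection_k: float = 1.0,
    subtract_ko: bool = True,
) -> ActivityRatio:
    """Variant activity relative to wild type, knock-out-referenced.

    ``ratio_to_wt`` is the ratio of medians with the knock-out median
    subtracted from both (the default; ``subtract_ko=False`` divides raw
    medians).  ``median_of_ratios`` aggregates the alternative order
    (per-replicate ratios, then median).  ``below_detection`` marks variants
    whose median rate is within ``detection_k``·IQR of the knock-out median.
    """
    v = np.asarray(variant_rates, float)
    wt = np.asarray(wt_rates, float)
    ko = np.asarray(ko_rates, float)
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("need >= 2 replicates for WT and knock-out controls")
    m_v, m_wt, m_ko = map(lambda x: float(np.median(x)), (v, wt, ko))
    if m_wt <= m_ko:
        raise ValueError(
            "assay invalid: WT median rate does not exceed knock-out median"
        )
    if subtract_ko:
        ratio = (m_v - m_ko) / (m_wt - m_ko)
        per_rep = (v - m_ko) / (m_wt - m_ko)
    else:
        ratio = m_v / m_wt
        per_rep = v / m_wt
    below = m_v <= m_ko + detection_k * _iqr(ko)
    return ActivityRatio(
        ratio_to_wt=float(ratio),
        median_rate=m_v,
        iqr=_iqr(v),
        n_replicates=len(v),
        below_detection=bool(below),
        ratio_no_subtraction=float(m_v / m_wt),
        median_of_ratios=float(np.median(per_rep)),
    )


def saturation_check(
    positive_control_rate: float,
    reaction_rates: Sequence[float],
) -> list[bool]:
    """Flag reactions whose implied product concentration reaches the
    fully-methylated positive control's.

    The positive control contains the product concentration corresponding to
    complete methylation of the mRNA, so any reaction whose rate is at least
    the control rate has saturated the assay.
    """
    if positive_control_rate <= 0:
        raise ValueError("positive control rate must be > 0")
    return [float(r) >= positive_control_rate for r in reaction_rates]
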