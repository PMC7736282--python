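"""Melting-temperature and activity epistasis between mutations.

For each single mutation the effect on the first melting transition is
ΔT_m = T_m1(mutant) − T_m1(WT).  For a multi-mutant the additive (null)
expectation is the sum of its constituent single-mutation ΔT_m values; the
epistatic deviation is observed − expected, so a negative deviation means
the combination is worse than additivity predicts (negative epistasis).

Activity epistasis is reported both on the linear scale (additivity of
activity-ratio changes) and as a multiplicative null on log ratios; for
below-detection (censored) variants the deviation is a bound, not a point
estimate.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

_MUT_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


@dataclass(frozen=True)
class Mutation:
    wt: str
    position: int
    mutant: str

    @classmethod
    def parse(cls, token: str) -> "Mutation":
        m = _MUT_RE.match(token.strip())
        if not m:
            raise ValueError(f"cannot parse mutation {token!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mutant}"


@dataclass
class VariantRecord:
    """One enzyme variant with its measured phenotypes."""

    name: str
    mutations: tuple[Mutation, ...]
    tm1: float | None = None              # °C
    activity: float | None = None         # ratio to WT
    red_shift: float | None = None        # nm
    below_detection: bool = False
    expression_tag: str | None = None

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError(f"{self.name}: duplicate mutated positions")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "VariantRecord":
        """Build from a dash-separated mutation name like 'K41D-A201R'
        ('WT' gives the empty mutation list)."""
        if name.upper() == "WT":
            return cls(name="WT", mutations=(), **kwargs)
        muts = tuple(Mutation.parse(tok) for tok in name.split("-"))
        return cls(name=name, mutations=muts, **kwargs)

    @property
    def is_wt(self) -> bool:
        return not self.mutations


@dataclass
class EffectTable:
    """Per-single-mutation effects relative to wild type."""

    wt: VariantRecord
    delta_tm: dict[Mutation, float]
    delta_activity: dict[Mutation, float]


@dataclass
class EpistasisResult:
    variant: str
    observed_delta_tm: float
    expected_delta_tm: float
    deviation: float
    observed_delta_activity: float | None = None
    expected_delta_activity: float | None = None
    activity_deviation: float | None = None
    log_activity_deviation: float | None = None
    censored: bool = False


def _find_wt(variants: Sequence[VariantRecord]) -> VariantRecord:
    wts = [v for v in variants if v.is_wt]
    if not wts:
        raise ValueError("wild-type record (empty mutation list) missing")
    return wts[0]


def single_effects(variants: Sequence[VariantRecord]) -> EffectTable:
    """ΔT_m and Δactivity of every single mutant relative to WT."""
    wt = _find_wt(variants)
    if wt.tm1 is None:
        raise ValueError("WT Tm1 missing")
    d_tm, d_act = {}, {}
    for v in variants:
        if len(v.mutations) != 1:
            continue
        mut = v.mutations[0]
        if v.tm1 is not None:
            d_tm[mut] = v.tm1 - wt.tm1
        if v.activity is not None and wt.activity is not None:
            d_act[mut] = v.activity - wt.activity
    return EffectTable(wt, d_tm, d_act)


def epistasis(
    variants: Sequence[VariantRecord],
    effects: EffectTable | None = None,
) -> list[EpistasisResult]:
    """Observed vs additive-expected ΔT_m for every variant with all
    constituent single mutants available.

    Multi-mutants missing a constituent single are skipped with a warning.
    Activity deviations are also computed (linear and log/multiplicative
    null); censored (below-detection) activities enter as 0 and mark the
    result as a bound.
    """
    if effects is None:
        effects = single_effects(variants)
    wt = effects.wt
    results = []
    for v in variants:
        if v.tm1 is None:
            continue
        observed = v.tm1 - wt.tm1
        if v.is_wt or len(v.mutations) == 1:
            exp = observed  # singles define the additive scale: deviation 0
        else:
            missing = [m for m in v.mutations if m not in effects.delta_tm]
            if missing:
                warnings.warn(
                    f"{v.name}: no single-mutant data for "
                    f"{', '.join(map(str, missing))}; skipped"
                )
                continue
            exp = sum(effects.delta_tm[m] for m in v.mutations)
        res = EpistasisResult(
            variant=v.name,
            observed_delta_tm=observed,
            expected_delta_tm=float(exp),
            deviation=float(observed - exp),
            censored=v.below_detection,
        )
        if (
            v.activity is not None
            and wt.activity is not None
            and all(m in effects.delta_activity for m in v.mutations)
        ):
            act = 0.0 if v.below_detection else v.activity
            obs_a = act - wt.activity
            exp_a = (
                obs_a
                if len(v.mutations) <= 1
                else sum(effects.delta_activity[m] for m in v.mutations)
            )
            res.observed_delta_activity = float(obs_a)
            res.expected_delta_activity = float(exp_a)
            res.activity_deviation = float(obs_a - exp_a)
            # multiplicative null on ratios; undefined on censored/zero values
            ratios = [wt.activity + effects.delta_activity[m] for m in v.mutations]
            if act > 0 and all(r > 0 for r in ratios) and wt.activity > 0:
                exp_log = sum(math.log(r / wt.activity) for r in ratios)
                obs_log = math.log(act / wt.activity)
                res.log_activity_deviation = (
                    0.0 if len(v.mutations) <= 1 else float(obs_log - exp_log)
                )
        results.append(res)
    return results
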