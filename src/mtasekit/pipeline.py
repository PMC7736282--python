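"""End-to-end orchestration: melt → activity → epistasis → classification.

The pipeline reads the per-stage input tables named in a config file (YAML
key-value), runs the stages in dependency order and joins everything into a
single variant-summary table: T_m1, unfolding red-shift, activity ratio,
detection flag, ΔT_m, epistatic deviation and fitness class per variant.
Every run logs the package version, the config hash and the seed into the
output header, so reruns are attributable and deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mtasekit import io as mio
from mtasekit.activity import activity_ratio, initial_rate
from mtasekit.classify import ClassificationThresholds, classify
from mtasekit.epistasis import VariantRecord, epistasis, single_effects
from mtasekit.melt import build_melt_curve, fit_replicates

log = logging.getLogger("mtasekit.pipeline")


@dataclass
class PipelineConfig:
    melt_spectra: str | None = None
    activity_traces: str | None = None
    wt_label: str = "WT"
    ko_label: str = "K175C"
    out_dir: str = "mtasekit_out"
    seed: int = 0
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    detection_k: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = ClassificationThresholds(**th)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.melt_spectra is None and self.activity_traces is None:
            raise ValueError("config names no inputs: nothing to run")
        for label, path in (
            ("melt_spectra", self.melt_spectra),
            ("activity_traces", self.activity_traces),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")

    def digest(self) -> str:
        payload = {
            k: (vars(v) if isinstance(v, ClassificationThresholds) else v)
            for k, v in vars(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("melt")
def _run_melt(cfg: PipelineConfig) -> pd.DataFrame:
    spectra = mio.read_spectra_table(cfg.melt_spectra)
    rows = []
    for sample, reps in spectra.items():
        curves = [build_melt_curve(s) for s in reps.values()]
        summary = fit_replicates(curves)
        rows.append(
            {
                "variant": sample,
                "tm1": summary["T_m1_median"],
                "red_shift": summary["red_shift_median"],
                "n_melt_replicates": len(curves),
                "n_converged": summary["n_converged"],
            }
        )
    return pd.DataFrame(rows)


@_stage("activity")
def _run_activity(cfg: PipelineConfig) -> pd.DataFrame:
    traces = mio.read_traces_table(cfg.activity_traces)
    for label in (cfg.wt_label, cfg.ko_label):
        if label not in traces:
            raise ValueError(f"control sample {label!r} missing from traces")
    rates = {
        s: [initial_rate(tr).initial_rate for tr in reps]
        for s, reps in traces.items()
    }
    rows = []
    for sample, r in rates.items():
        ar = activity_ratio(
            r, rates[cfg.wt_label], rates[cfg.ko_label], detection_k=cfg.detection_k
        )
        rows.append(
            {
                "variant": sample,
                "activity": ar.ratio_to_wt,
                "below_detection": ar.below_detection,
                "n_activity_replicates": ar.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | str | Path) -> pd.DataFrame:
    """Run all configured stages and write the joined variant summary.

    Returns the summary table; per-stage CSVs and the summary (with a
    provenance header) land in ``config.out_dir``.
    """
    from mtasekit import __version__

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    np.random.seed(config.seed % (2**31))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run: version=%s config=%s seed=%d", __version__, config.digest(),
             config.seed)

    frames = []
    if config.melt_spectra:
        melt_df = _run_melt(config)
        melt_df.to_csv(out / "melt_fits.csv", index=False)
        frames.append(melt_df.set_index("variant"))
    if config.activity_traces:
        act_df = _run_activity(config)
        act_df.to_csv(out / "activity.csv", index=False)
        frames.append(act_df.set_index("variant"))
    summary = pd.concat(frames, axis=1).reset_index().rename(
        columns={"index": "variant"}
    )

    records = {}
    for row in summary.itertuples():
        name = row.variant if row.variant != config.ko_label else row.variant
        try:
            records[row.variant] = VariantRecord.from_name(
                "WT" if row.variant == config.wt_label else row.variant,
                tm1=getattr(row, "tm1", None),
                activity=getattr(row, "activity", None),
                red_shift=getattr(row, "red_shift", None),
                below_detection=bool(getattr(row, "below_detection", False)),
            )
        except ValueError:
            log.warning("cannot parse variant name %r; kept unannotated",
                        row.variant)

    variants = list(records.values())
    has_wt = any(v.is_wt for v in variants)
    if has_wt and all(v.tm1 is not None for v in variants):
        effects = single_effects(variants)
        epi = {
            r.variant: r for r in epistasis(variants, effects)
        }
        summary["delta_tm"] = [
            epi[records[v].name].observed_delta_tm
            if v in records and records[v].name in epi else np.nan
            for v in summary["variant"]
        ]
        summary["epistasis_deviation"] = [
            epi[records[v].name].deviation
            if v in records and records[v].name in epi else np.nan
            for v in summary["variant"]
        ]
    if has_wt and {"tm1", "red_shift", "activity"} <= set(summary.columns):
        wt_rec = next(v for v in variants if v.is_wt)
        classes = []
        for v in summary["variant"]:
            if v not in records:
                classes.append("unclassifiable")
                continue
            try:
                classes.append(classify(records[v], wt_rec, config.thresholds).value)
            except ValueError as exc:
                log.warning("%s", exc)
                classes.append("unclassifiable")
        summary["fitness_class"] = classes

    path = out / "variant_summary.csv"
    with open(path, "w") as fh:
        fh.write(
            f"# mtasekit {__version__} | config {config.digest()} | "
            f"seed {config.seed}\n"
        )
        summary.to_csv(fh, index=False)
    return summary
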