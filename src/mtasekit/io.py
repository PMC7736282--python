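"""Readers for the tabular instrument formats the pipeline consumes."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from mtasekit.activity import KineticTrace
from mtasekit.melt import EmissionSpectrum


def read_spectra_table(path) -> dict[str, dict[int, list[EmissionSpectrum]]]:
    """Long-format emission spectra: columns sample, [replicate,]
    temperature, wavelength, intensity (CSV or TSV by extension).

    Returns ``{sample: {replicate: [EmissionSpectrum, ...]}}``; a missing
    replicate column means one replicate per sample.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"temperature", "wavelength", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "sample" not in df.columns:
        df["sample"] = "sample"
    if "replicate" not in df.columns:
        df["replicate"] = 1
    out: dict[str, dict[int, list[EmissionSpectrum]]] = defaultdict(dict)
    for (sample, rep), grp in df.groupby(["sample", "replicate"], sort=False):
        spectra = []
        for temp, g in grp.groupby("temperature", sort=True):
            g = g.sort_values("wavelength")
            spectra.append(
                EmissionSpectrum(
                    float(temp),
                    g["wavelength"].to_numpy(float),
                    g["intensity"].to_numpy(float),
                )
            )
        out[str(sample)][int(rep)] = spectra
    return dict(out)


def read_traces_table(path) -> dict[str, list[KineticTrace]]:
    """Kinetic traces, long format (sample, replicate, time_min, intensity)
    or plate-reader wide format (time_min followed by one column per sample).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    out: dict[str, list[KineticTrace]] = defaultdict(list)
    if {"sample", "time_min", "intensity"} <= set(df.columns):
        if "replicate" not in df.columns:
            df["replicate"] = 1
        conc = "protein_concentration" in df.columns
        for (sample, _), grp in df.groupby(["sample", "replicate"], sort=False):
            grp = grp.sort_values("time_min")
            out[str(sample)].append(
                KineticTrace(
                    grp["time_min"].to_numpy(float),
                    grp["intensity"].to_numpy(float),
                    sample=str(sample),
                    protein_concentration=(
                        float(grp["protein_concentration"].iloc[0]) if conc else None
                    ),
                )
            )
    elif "time_min" in df.columns:
        t = df["time_min"].to_numpy(float)
        for col in df.columns:
            if col == "time_min":
                continue
            # wide format: replicates as 'NAME.1', 'NAME.2' suffixes
            sample = col.rsplit(".", 1)[0]
            out[sample].append(
                KineticTrace(t, df[col].to_numpy(float), sample=sample)
            )
    else:
        raise ValueError(f"{path}: unrecognised trace table layout")
    return dict(out)
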