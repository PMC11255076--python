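"""CSV trace format and YAML configuration round-tripping.

Traces are stored as plain CSV with one row per 30-s sample and the exact
header ``subject,condition,time_min,ve_lpm,petco2_mmhg,segment`` — the
study's native format is unpublished and group data at 30-s resolution are
tiny, so a text format keeps everything inspectable.  Units are embedded in
the column (and JSON key) names to prevent unit drift.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chemoreflex import ChemoreflexParams
from .neuropool import CanonicalParams
from .synthetic import AIR, CO2_3PCT, GeneratorConfig, TraceSet, default_protocol

__all__ = [
    "TRACE_COLUMNS",
    "read_traces",
    "write_traces",
    "load_config",
    "dump_config",
    "config_to_dict",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["subject", "condition", "time_min", "ve_lpm", "petco2_mmhg", "segment"]
_CONDITIONS = {AIR, CO2_3PCT}


class TraceFormatError(ValueError):
    """Malformed trace CSV (missing columns, bad rows, non-monotone time)."""


def write_traces(traces: Sequence[TraceSet], path: str | Path) -> None:
    """Write traces as CSV; float values round-trip at full precision."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject": tr.subject,
                    "condition": tr.condition,
                    "time_min": tr.time_min,
                    "ve_lpm": tr.ve_lpm,
                    "petco2_mmhg": tr.petco2_mmhg,
                    "segment": tr.segments,
                }
            )
        )
    # %.17g round-trips any float64 exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_traces(path: str | Path, known_segments: set[str] | None = None) -> list[TraceSet]:
    """Read a trace CSV back into per-subject TraceSets.

    Validates the header, per-row values and strict time monotonicity within
    each subject; malformed rows are rejected with their line number.
    """
    df = pd.read_csv(
        path,
        dtype={"subject": str, "condition": str, "segment": str},
        float_precision="round_trip",
    )
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required columns {missing}")
    if known_segments is None:
        known_segments = {s.label for s in default_protocol().segments}

    for col in ("time_min", "ve_lpm", "petco2_mmhg"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise TraceFormatError(
                f"{path}: non-numeric {col} at line {int(bad[0]) + 2}"  # +2: header + 1-based
            )
    bad_cond = df.index[~df["condition"].isin(_CONDITIONS)]
    if len(bad_cond):
        raise TraceFormatError(
            f"{path}: unknown condition {df.loc[bad_cond[0], 'condition']!r} "
            f"at line {int(bad_cond[0]) + 2}"
        )
    bad_seg = df.index[~df["segment"].isin(known_segments)]
    if len(bad_seg):
        raise TraceFormatError(
            f"{path}: unknown segment label {df.loc[bad_seg[0], 'segment']!r} "
            f"at line {int(bad_seg[0]) + 2}"
        )

    traces: list[TraceSet] = []
    if df.empty:
        logger.warning("%s: header-only trace file, returning no traces", path)
        return traces
    for (subject, condition), sub in df.groupby(["subject", "condition"], sort=False):
        t = sub["time_min"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise TraceFormatError(
                f"{path}: non-increasing time for subject {subject!r} "
                f"at line {int(sub.index[k + 1]) + 2}"
            )
        traces.append(
            TraceSet(
                subject=str(subject),
                condition=str(condition),
                time_min=t,
                ve_lpm=sub["ve_lpm"].to_numpy(float),
                petco2_mmhg=sub["petco2_mmhg"].to_numpy(float),
                segments=sub["segment"].to_numpy(str),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# configuration


def config_to_dict(config: GeneratorConfig) -> dict:
    """Flatten a GeneratorConfig into a plain YAML-safe mapping."""
    c = config.chemo_truth
    l = config.ltf_truth
    return {
        "chemoreflex": {
            "Gc_lpm_per_mmhg": c.Gc,
            "Gp_lpm_per_mmhg": c.Gp,
            "tau_c_s": c.tau_c,
            "tau_p_s": c.tau_p,
            "delay_c_s": c.delay_c,
            "delay_p_s": c.delay_p,
        },
        "ltf": {
            "wn_rad_per_min": l.wn,
            "zeta": l.zeta,
            "B_lpm": l.B,
            "baseline_lpm": l.baseline,
            "onset_delay_min": l.onset_delay,
        },
        "drive_amplitude_lpm": dict(config.drive_amplitude_lpm),
        "drive_tau_min": config.drive_tau_min,
        "pet_dev_co2_mmhg": config.pet_dev_co2_mmhg,
        "pet_dev_air_mmhg": config.pet_dev_air_mmhg,
        "pet_air_transient_min": config.pet_air_transient_min,
        "pet_tau_min": config.pet_tau_min,
        "rest_ve_lpm": config.rest_ve_lpm,
        "pet_baseline_mmhg": config.pet_baseline_mmhg,
        "subject_sd_lpm": config.subject_sd_lpm,
        "noise_sd_lpm": config.noise_sd_lpm,
        "pet_noise_sd_mmhg": config.pet_noise_sd_mmhg,
        "n_subjects": config.n_subjects,
        "seed": config.seed,
    }


def _config_from_dict(d: Mapping) -> GeneratorConfig:
    kw = {}
    if "chemoreflex" in d:
        c = d["chemoreflex"]
        kw["chemo_truth"] = ChemoreflexParams(
            Gc=c["Gc_lpm_per_mmhg"],
            Gp=c["Gp_lpm_per_mmhg"],
            tau_c=c.get("tau_c_s", 120.0),
            tau_p=c.get("tau_p_s", 15.0),
            delay_c=c.get("delay_c_s", 10.0),
            delay_p=c.get("delay_p_s", 6.0),
        )
    if "ltf" in d:
        l = d["ltf"]
        kw["ltf_truth"] = CanonicalParams(
            wn=l["wn_rad_per_min"],
            zeta=l["zeta"],
            A=0.0,
            B=l["B_lpm"],
            baseline=l.get("baseline_lpm", 0.0),
            onset_delay=l.get("onset_delay_min", 0.0),
            time_unit="min",
        )
    for key in (
        "drive_amplitude_lpm",
        "drive_tau_min",
        "pet_dev_co2_mmhg",
        "pet_dev_air_mmhg",
        "pet_air_transient_min",
        "pet_tau_min",
        "rest_ve_lpm",
        "pet_baseline_mmhg",
        "subject_sd_lpm",
        "noise_sd_lpm",
        "pet_noise_sd_mmhg",
        "n_subjects",
        "seed",
    ):
        if key in d:
            kw[key] = d[key]
    return GeneratorConfig(**kw)


def load_config(path: str | Path | None) -> GeneratorConfig:
    """Load a YAML config; missing keys take the study-condition defaults."""
    if path is None:
        return GeneratorConfig()
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return _config_from_dict(d)


def dump_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
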