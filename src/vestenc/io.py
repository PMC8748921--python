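"""Delimited-text readers and writers for stimuli, spikes, and cohorts.

Formats:

* stimulus CSV — header ``time_s,pitch_velocity_dps,linear_accel_g`` plus
  optional ``accel_forward_g,accel_vertical_g`` axes;
* spike file — one spike time (s) per line;
* rate CSV — header ``time_s,rate_sps``;
* cohort manifest — YAML listing recordings, conditions, seeds, and ground
  truth, next to the per-recording data files.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .ln_cascade import SigmoidParams
from .spike_processing import RateTrace
from .synthetic import (
    AfferentGroundTruth,
    Cohort,
    CohortConfig,
    SimulatedRecording,
    StimulusParams,
    StimulusTrace,
)

__all__ = [
    "write_stimulus_csv",
    "read_stimulus_csv",
    "write_spike_times",
    "read_spike_times",
    "write_rate_csv",
    "read_rate_csv",
    "save_cohort",
    "load_cohort",
]


def write_stimulus_csv(trace: StimulusTrace, path: str) -> None:
    cols = {
        "time_s": trace.t,
        "pitch_velocity_dps": trace.pitch_velocity,
        "linear_accel_g": trace.linear_acceleration,
    }
    if trace.accel_forward is not None:
        cols["accel_forward_g"] = trace.accel_forward
        cols["accel_vertical_g"] = trace.accel_vertical
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_stimulus_csv(path: str, condition: str = "passive_low") -> StimulusTrace:
    df = pd.read_csv(path)
    for required in ("time_s", "pitch_velocity_dps", "linear_accel_g"):
        if required not in df.columns:
            raise ValueError(f"stimulus CSV missing column {required!r}")
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return StimulusTrace(
        t=t,
        pitch_velocity=df["pitch_velocity_dps"].to_numpy(float),
        linear_acceleration=df["linear_accel_g"].to_numpy(float),
        condition=condition,
        sample_rate=fs,
        accel_forward=df["accel_forward_g"].to_numpy(float)
        if "accel_forward_g" in df
        else None,
        accel_vertical=df["accel_vertical_g"].to_numpy(float)
        if "accel_vertical_g" in df
        else None,
    )


def write_spike_times(spike_times: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(spike_times, float), fmt="%.9f")


def read_spike_times(path: str) -> np.ndarray:
    arr = np.loadtxt(path, ndmin=1, dtype=float)
    return arr


def write_rate_csv(rate: RateTrace, path: str) -> None:
    pd.DataFrame({"time_s": rate.t, "rate_sps": rate.rate}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_rate_csv(path: str) -> RateTrace:
    df = pd.read_csv(path)
    return RateTrace(t=df["time_s"].to_numpy(float), rate=df["rate_sps"].to_numpy(float))


def _truth_to_dict(truth: AfferentGroundTruth) -> dict:
    d = {
        "organ": truth.organ,
        "regularity": truth.regularity,
        "resting_rate": truth.resting_rate,
        "response_lead_s": truth.response_lead_s,
        "isi_shape": truth.isi_shape,
        "sv": truth.sv,
        "sa": truth.sa,
        "sj": truth.sj,
    }
    if isinstance(truth.nonlinearity, SigmoidParams):
        d["nonlinearity"] = asdict(truth.nonlinearity)
    else:
        d["nonlinearity"] = truth.nonlinearity
    return d


def _truth_from_dict(d: dict) -> AfferentGroundTruth:
    nl = d["nonlinearity"]
    if isinstance(nl, dict):
        nl = SigmoidParams(**nl)
    return AfferentGroundTruth(
        organ=d["organ"],
        regularity=d["regularity"],
        resting_rate=d["resting_rate"],
        response_lead_s=d["response_lead_s"],
        isi_shape=d["isi_shape"],
        sv=d["sv"],
        sa=d["sa"],
        sj=d["sj"],
        nonlinearity=nl,
    )


def save_cohort(cohort: Cohort, outdir: str) -> str:
    """Write a cohort to delimited-text files plus a YAML manifest.

    Returns the manifest path.  Layout: ``stimuli/<condition>.csv``,
    ``spikes/<afferent>__<condition>.txt``, ``spikes/<afferent>__rest.txt``.
    """
    os.makedirs(os.path.join(outdir, "stimuli"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "spikes"), exist_ok=True)
    manifest: dict = {
        "seed": cohort.seed,
        "sample_rate": cohort.config.stimulus_params.sample_rate,
        "resting_duration_s": cohort.config.resting_duration_s,
        "stimuli": {},
        "afferents": {},
        "recordings": [],
    }
    for cond, stim in cohort.stimuli.items():
        rel = os.path.join("stimuli", f"{cond}.csv")
        write_stimulus_csv(stim, os.path.join(outdir, rel))
        manifest["stimuli"][cond] = rel
    for aff_id, truth in cohort.truths.items():
        rel = os.path.join("spikes", f"{aff_id}__rest.txt")
        write_spike_times(cohort.resting_spikes[aff_id], os.path.join(outdir, rel))
        manifest["afferents"][aff_id] = {
            "truth": _truth_to_dict(truth),
            "resting_spikes": rel,
        }
    for rec in cohort.recordings:
        rel = os.path.join("spikes", f"{rec.afferent_id}__{rec.condition}.txt")
        write_spike_times(rec.spike_times, os.path.join(outdir, rel))
        manifest["recordings"].append(
            {
                "afferent_id": rec.afferent_id,
                "condition": rec.condition,
                "spikes": rel,
                "seed": rec.seed,
            }
        )
    path = os.path.join(outdir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_cohort(outdir: str) -> Cohort:
    """Reconstruct a cohort from ``save_cohort`` output."""
    with open(os.path.join(outdir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    stimuli = {
        cond: read_stimulus_csv(os.path.join(outdir, rel), condition=cond)
        for cond, rel in manifest["stimuli"].items()
    }
    truths, resting = {}, {}
    for aff_id, entry in manifest["afferents"].items():
        truths[aff_id] = _truth_from_dict(entry["truth"])
        resting[aff_id] = read_spike_times(os.path.join(outdir, entry["resting_spikes"]))
    recordings = []
    for rec in manifest["recordings"]:
        recordings.append(
            SimulatedRecording(
                stimulus=stimuli[rec["condition"]],
                spike_times=read_spike_times(os.path.join(outdir, rec["spikes"])),
                truth=truths[rec["afferent_id"]],
                seed=rec["seed"],
                afferent_id=rec["afferent_id"],
            )
        )
    config = CohortConfig(
        conditions=tuple(stimuli),
        duration_s=next(iter(stimuli.values())).duration if stimuli else 0.0,
        resting_duration_s=manifest["resting_duration_s"],
        stimulus_params=StimulusParams(sample_rate=manifest["sample_rate"]),
    )
    return Cohort(
        recordings=recordings,
        resting_spikes=resting,
        truths=truths,
        stimuli=stimuli,
        config=config,
        seed=manifest["seed"],
    )
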