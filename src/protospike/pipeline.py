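"""Composable pipeline binding the analysis stages together.

A pipeline config is a JSON document: a global seed, an output
directory and an ordered list of stages with per-stage parameter
blocks.  Each stage writes its own JSON result; a combined report (plus
a human-readable summary) is written at the end.  Runs are reproducible:
the report records the seed and a hash of the config, and identical
config + seed produce identical output (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import boolgates, dielectric, impedance, io, izhikevich, spectral, spikes, synthgen
from .errors import ProtospikeError

log = logging.getLogger("protospike")


@dataclass(frozen=True)
class StageSpec:
    name: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    stages: list
    seed: int = 0
    out_dir: str = "protospike_out"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        stages = [StageSpec(s["name"], s.get("params", {})) for s in raw.get("stages", [])]
        return cls(stages=stages, seed=int(raw.get("seed", 0)),
                   out_dir=raw.get("out_dir", "protospike_out"),
                   log_level=raw.get("log_level", "INFO"))

    def as_dict(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir, "log_level": self.log_level,
                "stages": [{"name": s.name, "params": s.params} for s in self.stages]}


def _stage_simulate_recording(ctx, params, seed):
    cfg = synthgen.RecordingConfig(seed=seed, **params)
    trace, truth = synthgen.generate_spike_recording(cfg)
    ctx["trace"] = trace
    ctx["ground_truth"] = truth
    return {"n_samples": len(trace), "n_injected_spikes": len(truth),
            "duration_s": trace.duration}


def _stage_control(ctx, params, seed):
    trace = synthgen.generate_control_trace(params.get("duration", 3600.0),
                                            params.get("sample_interval", 1.0), seed)
    ctx["trace"] = trace
    return {"n_samples": len(trace), "max_abs_mV": float(np.abs(trace.potential).max())}


def _stage_izhikevich(ctx, params, seed):
    p = izhikevich.IzhikevichParams(**params.get("model", {}))
    stim = izhikevich.tc_stimulus(p, params.get("current", 5.0),
                                  dt=params.get("dt", 0.1),
                                  duration=params.get("duration", 1000.0),
                                  gain=params.get("gain", 0.1))
    ctx["stimulus"] = stim
    return {"n_samples": len(stim), "peak_mV": float(stim.potential.max())}


def _stage_spikes(ctx, params, seed):
    trace = _input_trace(ctx, params)
    cfg = spikes.DetectorConfig(**params.get("detector", {}))
    train = spikes.detect_spikes(trace, cfg)
    out = {"n_spikes": len(train)}
    if len(train):
        st = spikes.spike_statistics(train)
        out["amplitude_mV"] = st.amplitude.as_dict()
        if st.period is not None:
            out["period_s"] = st.period.as_dict()
    ctx["spike_train"] = train
    return out


def _stage_spectrum(ctx, params, seed):
    trace = _input_trace(ctx, params)
    pmap, curve = spectral.persistence_spectrum(
        trace, window_length=params.get("window_length", 1024),
        overlap=params.get("overlap", 0.5),
        summary=params.get("summary", "modal"))
    summary = spectral.magnitude_summary(curve)
    out = {"magnitude_dB": summary.as_dict()}
    if params.get("fit", True):
        keep = curve.frequency > 0
        sub = spectral.SpectrumCurve(curve.frequency[keep], curve.magnitude_db[keep])
        fit = spectral.fit_log3p1(sub)
        out["log3p1"] = {"a": fit.a, "b": fit.b, "c": fit.c,
                         "beta": spectral.power_law_exponent(fit),
                         **fit.gof.as_dict()}
    return out


def _stage_boolean(ctx, params, seed):
    trace = _input_trace(ctx, params)
    cfg = boolgates.ThresholdConfig(**params.get("thresholds", {}))
    table = boolgates.boolean_pipeline(trace, cfg)
    ctx["gate_table"] = table
    return {"n_rows": int(len(table)),
            "n_high": int(table["high"].sum()), "n_low": int(table["low"].sum())}


def _stage_fit_dielectric(ctx, params, seed):
    spec = io.read_capacitance_spectrum(params["input"]) if "input" in params \
        else ctx["capacitance_spectrum"]
    fit = dielectric.fit_logistic(spec)
    debye = dielectric.debye_from_logistic(fit.params)
    return {"logistic": {"A1": fit.params.A1, "A2": fit.params.A2,
                         "x0": fit.params.x0, "p": fit.params.p, **fit.gof.as_dict()},
            "debye": {"eps_s": debye.eps_s, "eps_inf": debye.eps_inf, "tau_s": debye.tau}}


def _stage_fit_impedance(ctx, params, seed):
    spec = io.read_impedance_spectrum(params["input"]) if "input" in params \
        else ctx["impedance_spectrum"]
    model = params.get("model", "randles")
    if model == "randles":
        fit = impedance.fit_randles(spec)
        return {"randles": {"Rs": fit.params.Rs, "Cdl": fit.params.Cdl,
                            "Rct": fit.params.Rct, "Zw": fit.params.Zw,
                            **fit.gof.as_dict()}}
    if model == "exp3p2":
        fit = impedance.fit_exp3p2(spec.frequency, np.abs(spec.Z))
        return {"exp3p2": {"a": fit.params.a, "b": fit.params.b, "c": fit.params.c,
                           **fit.gof.as_dict()}}
    raise ValueError(f"unknown impedance model {model!r}")


def _input_trace(ctx, params):
    if "input" in params:
        return io.read_trace(params["input"])
    if "trace" in ctx:
        return ctx["trace"]
    raise ValueError("stage needs an 'input' file or an upstream trace")


STAGES = {
    "simulate_recording": _stage_simulate_recording,
    "control": _stage_control,
    "izhikevich": _stage_izhikevich,
    "spikes": _stage_spikes,
    "spectrum": _stage_spectrum,
    "boolean": _stage_boolean,
    "fit_dielectric": _stage_fit_dielectric,
    "fit_impedance": _stage_fit_impedance,
}


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order and write the report bundle.

    Stage names are validated before anything runs.  On stage failure
    the run aborts with the stage name in the error; results of earlier
    stages remain on disk.
    """
    unknown = [s.name for s in cfg.stages if s.name not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; available: {sorted(STAGES)}")
    if not cfg.stages:
        raise ValueError("pipeline has no stages")
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log.info("run: config hash %s, seed %d", chash, cfg.seed)

    ctx: dict = {}
    results = {}
    for i, stage in enumerate(cfg.stages):
        stage_seed = (cfg.seed + 1000003 * i) % (2**31)
        log.info("stage %d: %s (seed %d)", i, stage.name, stage_seed)
        try:
            res = STAGES[stage.name](ctx, stage.params, stage_seed)
        except ProtospikeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage '{stage.name}' (index {i}) failed: {exc}") from exc
        key = f"{i:02d}_{stage.name}"
        results[key] = res
        io.write_json(res, out_dir / f"{key}.json")
    report = write_report(results, out_dir, seed=cfg.seed, config_hash_=chash)
    return report


def write_report(results: dict, out_dir, seed: int = 0, config_hash_: str = "") -> dict:
    """Write the combined JSON report and a human-readable summary."""
    if not results:
        raise ValueError("no results to report")
    report = {"seed": seed, "config_hash": config_hash_, "stages": results}
    io.write_json(report, Path(out_dir) / "report.json")
    lines = [f"protospike report (seed {seed}, config {config_hash_})"]
    for key, res in results.items():
        lines.append(f"- {key}: " + ", ".join(_headline(res)))
    io._atomic_write_text(Path(out_dir) / "report.txt", "\n".join(lines) + "\n")
    return report


def _headline(res: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in res.items():
        if isinstance(v, dict):
            out.extend(_headline(v, prefix=f"{prefix}{k}."))
        elif isinstance(v, float):
            out.append(f"{prefix}{k}={v:.6g}")
        else:
            out.append(f"{prefix}{k}={v}")
    return out
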