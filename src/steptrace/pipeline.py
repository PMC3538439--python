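"""Composable analysis pipelines with deterministic seeding.

A pipeline is an ordered list of stages, each a dict with a ``stage`` name
and its parameters, mirroring the standard rotary-motor analysis chain:
simulate a stepper (or load a trace), step-smooth it by (AR-)TV
denoising, wrap the idealized angles, form the ECF, shrink it, and invert
to a state density. Every intermediate artifact is written next to the
output, and a JSON report records parameters, seeds and per-stage
summaries.

A single global seed is expanded into independent per-stage substreams
keyed by (stage name, occurrence index) through ``numpy``'s SeedSequence,
so inserting an extra stage does not perturb the draws of later stages.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .ar import ar_tv_denoise, ar_tv_auto, estimate_ar1
from .density import (dominant_periodicity, ecf, reconstruct_density, shrink,
                      wrap_angles)
from .denoise import mean_shift_denoise, robust_tv_denoise, tv_denoise
from .dwell import compare_models, extract_dwells, fit_exponential, fit_powerlaw
from .io import write_pwc, write_spectrum, write_trace
from .synthetic import gen_rotational_stepper
from .trace import PiecewiseConstant, TimeSeries

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Ordered stage list, global seed, and output directory."""

    stages: list[dict[str, Any]]
    seed: int = 0
    out_dir: str = "."
    input_path: Optional[str] = None


def stage_seed(global_seed: int, name: str, occurrence: int) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    key = zlib.crc32(name.encode()) & 0xFFFFFFFF
    ss = np.random.SeedSequence([int(global_seed), key, int(occurrence)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _summary_of(obj) -> dict[str, Any]:
    if isinstance(obj, TimeSeries):
        return {"type": "TimeSeries", "n": len(obj),
                "mean": repr(float(obj.values.mean())),
                "sd": repr(float(obj.values.std()))}
    if isinstance(obj, PiecewiseConstant):
        return {"type": "PiecewiseConstant", "n": len(obj),
                "n_levels": int(obj.n_levels)}
    return {"type": type(obj).__name__}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the stages in order; returns (and writes) the JSON report.

    Known stages: ``simulate_stepper``, ``tv``, ``artv`` (fixed or
    estimated feedback), ``robust_tv``, ``mean_shift``, ``wrap``, ``ecf``,
    ``shrink``, ``density``, ``dwell``. A stage failure aborts with the
    stage name and cause.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {}
    if cfg.input_path:
        from .io import read_trace
        state["trace"] = read_trace(cfg.input_path)
    report: dict[str, Any] = {"version": __version__, "seed": cfg.seed,
                              "stages": []}
    counts: dict[str, int] = {}
    for stage in cfg.stages:
        stage = dict(stage)
        name = stage.pop("stage")
        occurrence = counts.get(name, 0)
        counts[name] = occurrence + 1
        sseed = stage_seed(cfg.seed, name, occurrence)
        try:
            entry = _run_stage(name, stage, sseed, state, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        entry.update({"stage": name, "params": stage, "substream_seed": sseed})
        report["stages"].append(entry)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _require(state: dict, key: str, name: str):
    if key not in state:
        raise ValueError(f"stage {name!r} needs a {key!r} from an earlier stage")
    return state[key]


def _run_stage(name: str, p: dict, sseed: int, state: dict,
               out: Path) -> dict[str, Any]:
    if name == "simulate_stepper":
        ts, seq = gen_rotational_stepper(
            steps_per_rev=int(p.get("steps_per_rev", 26)),
            dwell_mean=float(p.get("dwell_mean", 20)),
            n_revolutions=int(p.get("n_revolutions", 10)),
            seed=sseed,
            mod_weights=p.get("mod_weights"),
            angle_noise_sd=float(p.get("angle_noise_sd", 0.0)),
            sample_interval=float(p.get("sample_interval", 1.0)))
        state["trace"], state["states"] = ts, seq
        write_trace(ts, out / "trace.csv")
        return _summary_of(ts)
    if name in ("tv", "artv", "robust_tv", "mean_shift"):
        ts = _require(state, "trace", name)
        if name == "tv":
            pwc = tv_denoise(ts, float(p["gamma"]))
        elif name == "robust_tv":
            pwc = robust_tv_denoise(ts, float(p["gamma"]))
        elif name == "mean_shift":
            pwc = mean_shift_denoise(ts, float(p["W"]))
        else:
            if "a" in p and p["a"] is not None:
                pwc = ar_tv_denoise(ts, float(p["a"]), float(p["gamma"]))
                a = float(p["a"])
            else:
                pwc, a = ar_tv_auto(ts, float(p["gamma"]))
        state["pwc"] = pwc
        write_pwc(pwc, out / "steps.csv", ts.sample_interval)
        entry = _summary_of(pwc)
        if name == "artv":
            entry["a"] = repr(float(a))
        return entry
    if name == "wrap":
        pwc = _require(state, "pwc", name)
        state["angles"] = wrap_angles(pwc.per_sample)
        return {"type": "angles", "n": int(state["angles"].size)}
    if name == "ecf":
        angles = state.get("angles")
        if angles is None:
            pwc = _require(state, "pwc", name)
            angles = wrap_angles(pwc.per_sample)
        spec = ecf(angles, F_max=int(p.get("F_max", 100)))
        state["spectrum"] = spec
        write_spectrum(spec, out / "spectrum.csv")
        return {"type": "ECFSpectrum", "F_max": int(spec.freqs.max())}
    if name == "shrink":
        spec = _require(state, "spectrum", name)
        res = shrink(spec, mode=p.get("mode", "mad"))
        state["shrunk"] = res
        write_spectrum(spec, out / "spectrum_shrunk.csv", res)
        return {"type": "ShrinkageResult",
                "lambda": repr(res.lam), "zeta": repr(res.zeta),
                "kept": [int(f) for f in res.kept_freqs],
                "dominant_periodicity": dominant_periodicity(res)}
    if name == "density":
        res = _require(state, "shrunk", name)
        dens = reconstruct_density(res, grid_size=int(p.get("grid_size", 512)))
        state["density"] = dens
        with open(out / "density.csv", "w") as fh:
            fh.write("angle,density\n")
            for g, d in zip(dens.grid, dens.density):
                fh.write(f"{g:.15g},{d:.15g}\n")
        return {"type": "DensityEstimate", "integral": repr(dens.integral())}
    if name == "dwell":
        pwc = _require(state, "pwc", name)
        ts = state.get("trace")
        dt = ts.sample_interval if ts is not None else 1.0
        table = extract_dwells(pwc, dt)
        if table.empty or table.uncensored().size < 2:
            return {"type": "DwellTable", "n": 0, "note": "too few dwells"}
        fe = fit_exponential(table)
        entry = {"type": "DwellTable", "n": int(table.durations.size),
                 "exponential": {"rate": repr(fe.rate), "bic": repr(fe.bic)}}
        try:
            fp = fit_powerlaw(table, x_min=p.get("x_min"))
            delta, preferred = compare_models(fe, fp)
            entry["powerlaw"] = {"alpha": repr(fp.alpha), "bic": repr(fp.bic)}
            entry["delta_bic"] = repr(delta)
            entry["preferred"] = preferred
        except ValueError:
            pass
        return entry
    raise ValueError(f"unknown stage {name!r}")
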