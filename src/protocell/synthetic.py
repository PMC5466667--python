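"""Synthetic inputs: noisy release traces, composition series, parameter sets.

Everything the pipeline consumes can be generated here deterministically
from a seed, so all stages are testable offline.  Release traces follow
exponential sink kinetics F(t) = 1 - exp(-k t) with additive Gaussian
measurement noise clipped to [0, 1]; per-composition rates follow an
exact polynomial multiplier curve peaking at intermediate compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay import AssayGeometry, ReleaseTrace
from .networks import add_lipid_synthesis, build_pm1, build_pm2
from .physics import DEFAULT_CURVE_POINTS, PermeabilityCurve, PhysicsParams

__all__ = [
    "TraceGenSpec",
    "gen_release_trace",
    "gen_composition_series",
    "default_parameter_set",
    "build_model_from_config",
    "write_fixtures",
]


@dataclass
class TraceGenSpec:
    """Generator spec for one synthetic release trace.

    Exactly one of ``k_true`` (1/min) or ``P_true`` (m/s) must be given;
    a permeability is converted through the spherical-vesicle relation
    k = 3 P / r (inverse of the assay's rate-to-permeability conversion).
    """

    k_true: Optional[float] = None
    P_true: Optional[float] = None
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    times: Sequence[float] = tuple(range(0, 61, 2))  # min
    noise_sd: float = 0.0
    seed: int = 0
    composition: str = ""

    def rate(self) -> float:
        if (self.k_true is None) == (self.P_true is None):
            raise ValueError("give exactly one of k_true or P_true")
        if self.k_true is not None:
            return float(self.k_true)
        return 3.0 * self.P_true / (self.geometry.radius * 1e-9) * 60.0  # 1/min

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be >= 0")


def gen_release_trace(spec: TraceGenSpec) -> ReleaseTrace:
    """F(t) = 1 - exp(-k t) + Gaussian noise, clipped to [0, 1]; seeded."""
    k = spec.rate()
    t = np.asarray(list(spec.times), dtype=float)
    f = 1.0 - np.exp(-k * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return ReleaseTrace(
        times=t,
        fraction_released=np.clip(f, 0.0, 1.0),
        composition=spec.composition,
    )


DEFAULT_PEAK_CHI = 0.375
DEFAULT_PEAK_FACTOR = 10.0
DEFAULT_END_FACTOR = 2.0


def gen_composition_series(
    chis: Sequence[float],
    peak_chi: float = DEFAULT_PEAK_CHI,
    peak_factor: float = DEFAULT_PEAK_FACTOR,
    end_factor: float = DEFAULT_END_FACTOR,
    base_k: float = 0.01,  # 1/min at chi = 0
    noise_sd: float = 0.0,
    seed: int = 0,
    times: Sequence[float] = tuple(range(0, 61, 2)),
    geometry: AssayGeometry = AssayGeometry(),
) -> tuple[dict[float, float], list[ReleaseTrace], PermeabilityCurve]:
    """Per-composition true rates plus traces, with the generating curve.

    The underlying multiplier is the exact polynomial through (0, 1),
    (peak_chi, peak_factor), (1, end_factor); rates are base_k * f(chi).
    Returns ({chi: k_true}, traces, generating_curve).
    """
    if not 0.0 < peak_chi < 1.0:
        raise ValueError("peak_chi must be interior")
    if peak_factor <= 0 or end_factor <= 0:
        raise ValueError("factors must be positive")
    curve = PermeabilityCurve([(0.0, 1.0), (peak_chi, peak_factor), (1.0, end_factor)])
    rates = {float(chi): base_k * curve(float(chi)) for chi in chis}
    traces = [
        gen_release_trace(
            TraceGenSpec(
                k_true=k,
                geometry=geometry,
                times=times,
                noise_sd=noise_sd,
                seed=seed + i,
                composition=f"chi={chi:.3f}",
            )
        )
        for i, (chi, k) in enumerate(sorted(rates.items()))
    ]
    return rates, traces, curve


# ---------------------------------------------------------------------------
# Default parameter sets
# ---------------------------------------------------------------------------

_MODELS = {"pm1": build_pm1, "pm2": build_pm2}
_SCENARIOS = ("fixed_compartment", "reproducing", "assay")

#: lipid-synthesis rate constant, chosen so that surface growth keeps pace
#: with the osmotically driven volume growth of the default networks (and
#: the stationary cell size stays near the initial 200 nm radius)
DEFAULT_K_SYN = {"pm1": 0.05, "pm2": 0.05}
#: starting concentrations for the reproducing scenario (mol/m^3): metabolite
#: stocks plus fast species pre-set near their transported quasi-steady
#: levels, with an inert trapped-product ballast filling part of the budget
DEFAULT_REPRODUCING_INIT = {
    "pm1": {
        "AB": 12.2, "ACD": 6.6, "acd": 20.0, "L": 1.9,
        "A": 5.0, "B": 7.0, "C": 8.0, "D": 8.5, "P": 7.5, "w": 18.0,
    },
    "pm2": {
        "AB": 12.2, "AC": 0.9, "ACD": 6.6, "acd": 20.0, "L": 1.9,
        "A": 5.0, "B": 7.0, "C": 8.0, "D": 8.5, "P": 7.5, "w": 18.0,
    },
}


def default_parameter_set(model_name: str, scenario: str) -> dict:
    """Complete, documented config for a (model, scenario) pair.

    Returns a nested dict with ``network``, ``physics`` and ``scenario``
    blocks, round-trippable through the YAML config layer and consumable by
    both engines and the CLI.
    """
    if model_name not in _MODELS:
        raise ValueError(f"unknown model {model_name!r}; valid: {sorted(_MODELS)}")
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {sorted(_SCENARIOS)}")

    if scenario == "assay":
        return {
            "scenario": {
                "name": "assay",
                "chis": [0.0, 0.125, 0.25, 0.375, 0.5, 0.75, 1.0],
                "peak_chi": DEFAULT_PEAK_CHI,
                "peak_factor": DEFAULT_PEAK_FACTOR,
                "end_factor": DEFAULT_END_FACTOR,
                "base_k": 0.01,
                "noise_sd": 0.01,
                "seed": 2017,
                "times": list(range(0, 61, 2)),
                "geometry": {"radius": 200.0, "thickness": 3.0},
            }
        }

    model = _MODELS[model_name]()
    physics = PhysicsParams()
    if scenario == "reproducing":
        model = add_lipid_synthesis(model, k_syn=DEFAULT_K_SYN[model_name], k_d=0.02)
        init = dict(DEFAULT_REPRODUCING_INIT[model_name])
        horizon = 6000.0
    else:
        init = {}
        horizon = 2000.0
    return {
        "network": model.to_dict(),
        "physics": physics.to_dict(),
        "scenario": {
            "name": scenario,
            "model": model_name,
            "init_conc": init,
            "t_end": horizon,
            "seed": 0,
        },
    }


def build_model_from_config(config: dict):
    """(NetworkModel, PhysicsParams, scenario dict) from a config mapping."""
    from .networks import NetworkModel

    model = NetworkModel.from_dict(config["network"])
    physics = PhysicsParams.from_dict(config["physics"])
    return model, physics, dict(config.get("scenario", {}))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _format_float(x: float) -> str:
    return format(float(x), ".10g")


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Regenerate the packaged assay fixtures (byte-stable at fixed seed)."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_parameter_set("pm1", "assay")["scenario"]
    _, traces, _ = gen_composition_series(
        cfg["chis"],
        peak_chi=cfg["peak_chi"],
        peak_factor=cfg["peak_factor"],
        end_factor=cfg["end_factor"],
        base_k=cfg["base_k"],
        noise_sd=cfg["noise_sd"],
        seed=cfg["seed"],
        times=cfg["times"],
        geometry=AssayGeometry(**cfg["geometry"]),
    )
    trace_path = out / "assay_traces.csv"
    lines = ["time_min,fraction_released,composition,replicate"]
    for trace in traces:
        for t, f in zip(trace.times, trace.fraction_released):
            lines.append(
                f"{_format_float(t)},{_format_float(f)},{trace.composition},1"
            )
    trace_path.write_text("\n".join(lines) + "\n")
    cfg_path = out / "assay_config.yaml"
    cfg_path.write_text(yaml.safe_dump({"scenario": cfg}, sort_keys=True))
    return [trace_path, cfg_path]
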