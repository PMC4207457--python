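"""Experiment presets, run orchestration, provenance, and report generation.

A preset bundles the physical parameters of one published scenario (loop
size, density, stiffness, crossing/phantom flags) with a sampling schedule
and default analysis requests.  Every looped preset has a matched no-loop
control differing only in its loop list and run count (two no-loop runs for
ten looped runs at full scale).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (
    ContactMap,
    control_pair,
    ensemble_heatmap,
    facilitation_pair,
    facilitation_score,
    fish_distances,
    insulation_pair,
    insulation_score,
    intra_loop_score,
    loop_base_profile,
    radial_density,
    two_loop_summary,
)
from .dynamics import (
    DESK_SCHEDULE,
    PAPER_SCHEDULE,
    Ensemble,
    SamplingSchedule,
    run_dynamics,
)
from .initialize import prepare_start
from .model import LoopSpec, SimulationParameters

__all__ = [
    "ExperimentPreset",
    "preset_catalog",
    "get_preset",
    "control_for",
    "get_schedule",
    "simulate_scenario",
    "analyze_pair",
    "load_config",
    "save_config",
    "export_presets",
    "provenance_record",
]


@dataclass
class ExperimentPreset:
    """One named simulation scenario with its analysis requests."""

    name: str
    params: SimulationParameters
    analysis: dict = field(default_factory=dict)
    table_analogue: str = "custom"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "table_analogue": self.table_analogue,
            "analysis": self.analysis,
            **self.params.to_dict(),
        }


def _ring_length(loop_monomers: int) -> int:
    """Total ring length ~= 33x the loop size, rounded to an even count."""
    return 2 * round(50.0 * loop_monomers / 3.0)


def _one_loop(
    loop_monomers: int,
    bp_per_monomer: int = 500,
    stiffness_k: float = 3.0,
    volume_density: float = 0.02,
    crossing_allowed: bool = True,
    phantom: bool = False,
) -> SimulationParameters:
    n = _ring_length(loop_monomers)
    a = n // 2 - loop_monomers // 2
    return SimulationParameters(
        n_monomers=n,
        bp_per_monomer=bp_per_monomer,
        stiffness_k=stiffness_k,
        volume_density=volume_density,
        crossing_allowed=crossing_allowed,
        phantom=phantom,
        loops=[LoopSpec(a, a + loop_monomers)],
    )


def _default_analysis(loop_monomers: int) -> dict:
    ep = round(5 * loop_monomers / 3)  # 50 kb for the 30 kb loop
    return {
        "insulation": {"ep_distance": ep},
        "facilitation": {"ep_distance": ep},
    }


def preset_catalog() -> list[ExperimentPreset]:
    """All named scenarios, mirroring the published parameter sets, plus the
    auto-generated no-loop control of each distinct physics."""
    presets = [
        ExperimentPreset(
            "one_loop_15kb", _one_loop(30), _default_analysis(30), "loop size 15 kb"
        ),
        ExperimentPreset(
            "one_loop_30kb", _one_loop(60), _default_analysis(60), "default (30 kb loop)"
        ),
        ExperimentPreset(
            "one_loop_60kb", _one_loop(120), _default_analysis(120), "loop size 60 kb"
        ),
        ExperimentPreset(
            "small_flexible_2.5kb",
            _one_loop(10, bp_per_monomer=250, stiffness_k=2.0),
            _default_analysis(10),
            "2.5 kb loop, flexible fiber (250 bp/monomer, k=2)",
        ),
        ExperimentPreset(
            "density_1pct", _one_loop(60, volume_density=0.01),
            _default_analysis(60), "volume density 1%",
        ),
        ExperimentPreset(
            "density_2pct", _one_loop(60, volume_density=0.02),
            _default_analysis(60), "volume density 2% (default)",
        ),
        ExperimentPreset(
            "density_10pct", _one_loop(60, volume_density=0.10),
            _default_analysis(60), "volume density 10%",
        ),
        ExperimentPreset(
            "density_20pct", _one_loop(60, volume_density=0.20),
            _default_analysis(60), "volume density 20%",
        ),
        ExperimentPreset(
            "stiffness_k2", _one_loop(60, stiffness_k=2.0),
            _default_analysis(60), "lower stiffness (k=2)",
        ),
        ExperimentPreset(
            "stiffness_k4", _one_loop(60, stiffness_k=4.0),
            _default_analysis(60), "higher stiffness (k=4)",
        ),
        ExperimentPreset(
            "no_crossing", _one_loop(60, crossing_allowed=False),
            _default_analysis(60), "topo-II off (no fiber crossing)",
        ),
        ExperimentPreset(
            "phantom_chain", _one_loop(60, phantom=True),
            _default_analysis(60), "phantom chain (no excluded volume)",
        ),
    ]
    # two consecutive 60-monomer loops sharing the middle base (three bases)
    n = _ring_length(60)
    two = SimulationParameters(
        n_monomers=n,
        loops=[LoopSpec(n // 2 - 60, n // 2), LoopSpec(n // 2, n // 2 + 60)],
    )
    presets.append(
        ExperimentPreset(
            "two_loop", two,
            {**_default_analysis(60), "two_loop_summary": {}},
            "two consecutive loops",
        )
    )
    controls = [control_for(p) for p in presets]
    return presets + controls


def control_for(preset: ExperimentPreset) -> ExperimentPreset:
    """The matched no-loop control: identical physics, ``loops = []``."""
    return ExperimentPreset(
        name=preset.name + "_control",
        params=replace(preset.params, loops=[]),
        analysis={},
        table_analogue=preset.table_analogue + " (no-loop control)",
    )


def get_preset(name: str) -> ExperimentPreset:
    for p in preset_catalog():
        if p.name == name:
            return p
    known = ", ".join(p.name for p in preset_catalog())
    raise KeyError(f"unknown preset {name!r}; known presets: {known}")


def get_schedule(name: str) -> SamplingSchedule:
    try:
        return {"paper": PAPER_SCHEDULE, "desk": DESK_SCHEDULE}[name]
    except KeyError:
        raise KeyError(f"unknown schedule {name!r} (use 'paper' or 'desk')") from None


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[SimulationParameters, SamplingSchedule | None]:
    """Read a scenario configuration (YAML with SimulationParameters keys,
    optionally a nested ``schedule`` section)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    raw.pop("name", None)
    raw.pop("table_analogue", None)
    raw.pop("analysis", None)
    sched = raw.pop("schedule", None)
    params = SimulationParameters.from_dict(raw)
    schedule = SamplingSchedule.from_dict(sched) if sched else None
    return params, schedule


def save_config(path, params: SimulationParameters,
                schedule: SamplingSchedule | None = None, **extra) -> None:
    doc = {**extra, **params.to_dict()}
    if schedule is not None:
        doc["schedule"] = schedule.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def export_presets(directory) -> list[Path]:
    """Write every preset as a YAML scenario file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for p in preset_catalog():
        path = directory / f"{p.name}.yaml"
        save_config(path, p.params, name=p.name,
                    table_analogue=p.table_analogue, analysis=p.analysis)
        written.append(path)
    return written


def provenance_record(params: SimulationParameters,
                      schedule: SamplingSchedule, seed: int) -> dict:
    doc = json.dumps(
        {"params": params.to_dict(), "schedule": schedule.to_dict()},
        sort_keys=True,
    )
    return {
        "config_sha256": hashlib.sha256(doc.encode()).hexdigest(),
        "seed": int(seed),
        "code_version": __version__,
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _run_seed(seed: int, run: int) -> int:
    return (seed * 100_003 + 7919 * run + 1) % 2**31


def simulate_scenario(
    params: SimulationParameters,
    schedule: SamplingSchedule,
    seed: int,
    n_runs: int | None = None,
    progress: bool = False,
) -> list[Ensemble]:
    """Run all independent replicas of one scenario.

    Each run grows a fresh unentangled starting ring from its own seed, so
    replicas are initialization-independent; the run count defaults to the
    schedule's loop / no-loop run numbers.
    """
    if n_runs is None:
        n_runs = schedule.n_runs_loop if params.loops else schedule.n_runs_noloop
    out = []
    for r in range(n_runs):
        rs = _run_seed(seed, r)
        start = prepare_start(params, seed=rs)
        if progress:
            print(f"  run {r + 1}/{n_runs} (seed {rs}) ...", flush=True)
        out.append(run_dynamics(start, params, schedule, seed=rs))
    return out


def analyze_pair(
    loop_ensembles: list[Ensemble],
    noloop_ensembles: list[Ensemble],
    loop: LoopSpec,
    requests: dict,
) -> dict:
    """Build per-run heatmaps and evaluate the requested scores.

    ``requests`` maps operation names (insulation, facilitation, intra_loop,
    loop_base_profile, radial_density, fish, two_loop_summary) to their
    keyword options.  Returns a JSON-serializable report.
    """
    n = loop_ensembles[0].n_monomers
    if any(e.n_monomers != n for e in loop_ensembles + noloop_ensembles):
        raise ValueError("ensembles have mismatched monomer counts")
    loop_maps = [ensemble_heatmap(e) for e in loop_ensembles]
    noloop_maps = [ensemble_heatmap(e) for e in noloop_ensembles]
    report: dict = {"n_monomers": n, "results": {}}

    def _asdict(rr):
        return dataclasses.asdict(rr)

    for key, opts in requests.items():
        opts = dict(opts or {})
        if key == "insulation":
            rr = insulation_score(loop_maps, noloop_maps, loop, **opts)
            report["results"]["insulation"] = _asdict(rr)
        elif key == "facilitation":
            rr = facilitation_score(loop_maps, noloop_maps, loop, **opts)
            report["results"]["facilitation"] = _asdict(rr)
        elif key == "intra_loop":
            rr = intra_loop_score(loop_maps, noloop_maps, loop, **opts)
            report["results"]["intra_loop"] = _asdict(rr)
        elif key == "loop_base_profile":
            pooled_l = ensemble_heatmap(loop_ensembles)
            pooled_n = ensemble_heatmap(noloop_ensembles)
            base = opts.get("base", min(loop.anchor_a, loop.anchor_b))
            prof = loop_base_profile(pooled_l, pooled_n, base)
            report["results"]["loop_base_profile"] = {
                "base": prof.base,
                "offsets": prof.offsets.tolist(),
                "ratio": prof.ratio.tolist(),
            }
        elif key == "radial_density":
            prof = radial_density(loop_ensembles, loop, **opts)
            report["results"]["radial_density"] = {
                "bin_edges": prof.bin_edges.tolist(),
                "density": prof.density.tolist(),
                "control": prof.control.tolist(),
            }
        elif key == "fish":
            ep = opts.get("ep_distance", 180)
            pairs = {
                "insulation": insulation_pair(loop, n, ep),
                "facilitation": facilitation_pair(loop, n, ep),
                "control": control_pair(loop, n, ep),
            }
            fish = {}
            for arr_name, (i, j) in pairs.items():
                f = fish_distances(loop_ensembles, i, j)
                fish[arr_name] = {"i": i, "j": j, "mean": f.mean}
            fish["mean_change_insulation_pct"] = 100.0 * (
                fish["insulation"]["mean"] / fish["control"]["mean"] - 1.0
            )
            fish["mean_change_facilitation_pct"] = 100.0 * (
                1.0 - fish["facilitation"]["mean"] / fish["control"]["mean"]
            )
            report["results"]["fish"] = fish
        elif key == "two_loop_summary":
            pooled_l = ensemble_heatmap(loop_ensembles)
            report["results"]["two_loop_summary"] = two_loop_summary(
                pooled_l, opts.get("loops") or loop_ensembles[0].params.loops
            )
        else:
            raise ValueError(f"unknown analysis request {key!r}")
    return report
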