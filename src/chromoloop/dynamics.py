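"""Langevin-dynamics sampling of the equilibrium ensemble.

The integrator is a BAOAB splitting of Langevin dynamics with Andersen
velocity-resampling collisions layered on top; both thermostats preserve the
canonical distribution at kT = 1, and the contract here is the equilibrium
ensemble, not trajectory realism.  Conformations are recorded every
``steps_per_block`` steps ("blocks"); blocks before ``equilibration_blocks``
are discarded.

The default timestep and thermostat constants were fixed by
``validate_timestep``: the timestep must conserve kinetic energy in a
thermostat-free run to within 2% and produce no strand crossing with the
non-truncated (non-crossable) potential, verified by conservation of the
Alexander knot determinant.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import _kernels
from .model import Conformation, SimulationParameters

__all__ = [
    "SamplingSchedule",
    "PAPER_SCHEDULE",
    "DESK_SCHEDULE",
    "Ensemble",
    "BlowUpError",
    "run_dynamics",
    "equilibration_check",
    "validate_timestep",
    "NOT_SATURATED",
]

#: sentinel returned by equilibration_check for a never-saturating signal
NOT_SATURATED = -1


class BlowUpError(RuntimeError):
    """Dynamics produced non-finite coordinates (timestep too large?)."""


@dataclass(frozen=True)
class SamplingSchedule:
    """Block schedule and integrator constants for one scenario.

    ``timestep`` is in reduced time units (monomer diameter, kT, unit mass);
    ``friction`` is the Langevin friction of the O-step and
    ``thermostat_collision_rate`` the Andersen velocity-resampling rate, both
    per reduced time unit.
    """

    n_blocks: int = 80_000
    steps_per_block: int = 3000
    equilibration_blocks: int = 1000
    timestep: float = 0.015
    friction: float = 0.0
    thermostat_collision_rate: float = 0.1
    n_runs_loop: int = 10
    n_runs_noloop: int = 2

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if not 0 <= self.equilibration_blocks < self.n_blocks:
            raise ValueError("equilibration_blocks must be < n_blocks")

    @property
    def sampling_blocks(self) -> int:
        return self.n_blocks - self.equilibration_blocks

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingSchedule":
        return cls(**d)


#: the full-fidelity schedule (80,000 blocks of 3000 steps, 1000 discarded)
PAPER_SCHEDULE = SamplingSchedule()

#: reduced schedule with identical physics for desk-scale runs: several
#: shorter runs per scenario, pooled at analysis time
DESK_SCHEDULE = SamplingSchedule(
    n_blocks=900,
    steps_per_block=500,
    equilibration_blocks=600,
    n_runs_loop=8,
    n_runs_noloop=2,
)


@dataclass
class Ensemble:
    """Post-equilibration conformations of one run, with provenance.

    ``coords`` has shape (n_conformations, N, 3) in float32;
    ``diagnostics`` holds per-block arrays over *all* blocks of the run
    (block-averaged kinetic energy per monomer, max bond length, mean
    monomer displacement from the start).
    """

    coords: np.ndarray
    block_indices: np.ndarray
    params: SimulationParameters
    schedule: SamplingSchedule
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[1]

    def conformation(self, i: int) -> Conformation:
        return Conformation(self.coords[i].astype(np.float64))

    def to_xyz(self, directory, stride: int = 1) -> list:
        """Export recorded conformations as XYZ files (one per block)."""
        from pathlib import Path

        from .initialize import write_xyz

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for k in range(0, self.n_conformations, stride):
            path = directory / f"block{int(self.block_indices[k]):06d}.xyz"
            write_xyz(path, self.coords[k].astype(float),
                      comment=f"block {int(self.block_indices[k])} seed {self.seed}")
            written.append(path)
        return written

    def save(self, path) -> None:
        """Write the ensemble to an HDF5 container."""
        import json

        with h5py.File(path, "w") as fh:
            fh.create_dataset("coords", data=self.coords, compression="gzip")
            fh.create_dataset("block_indices", data=self.block_indices)
            for key, arr in self.diagnostics.items():
                fh.create_dataset(f"diagnostics/{key}", data=arr)
            fh.attrs["params"] = json.dumps(self.params.to_dict())
            fh.attrs["schedule"] = json.dumps(self.schedule.to_dict())
            fh.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path) -> "Ensemble":
        import json

        with h5py.File(path, "r") as fh:
            return cls(
                coords=fh["coords"][:],
                block_indices=fh["block_indices"][:],
                params=SimulationParameters.from_dict(json.loads(fh.attrs["params"])),
                schedule=SamplingSchedule.from_dict(json.loads(fh.attrs["schedule"])),
                seed=int(fh.attrs["seed"]),
                diagnostics={
                    key: fh[f"diagnostics/{key}"][:]
                    for key in fh.get("diagnostics", {})
                },
            )


def run_dynamics(
    start: Conformation,
    params: SimulationParameters,
    schedule: SamplingSchedule,
    seed: int,
) -> Ensemble:
    """Sample the equilibrium ensemble from ``start`` by Langevin dynamics.

    Deterministic for a given seed (single-threaded compiled kernel with its
    own seeded generator).  Raises :class:`BlowUpError` if coordinates go
    non-finite, naming the offending block.
    """
    if start.n_monomers != params.n_monomers:
        raise ValueError("start conformation size does not match parameters")
    n = params.n_monomers
    rng = np.random.default_rng(seed)
    x = np.ascontiguousarray(start.coords, dtype=np.float64).copy()
    v = rng.standard_normal((n, 3))

    loops = params.loop_pairs()
    loop_a = np.ascontiguousarray(loops[:, 0]) if len(loops) else np.empty(0, np.int64)
    loop_b = np.ascontiguousarray(loops[:, 1]) if len(loops) else np.empty(0, np.int64)
    excl = np.empty(0, dtype=np.int64)
    if params.exclude_loop_anchor_repulsion and len(loops):
        keys = [min(a, b) * n + max(a, b) for a, b in loops]
        excl = np.array(sorted(keys), dtype=np.int64)

    n_rec = schedule.n_blocks - schedule.equilibration_blocks
    rec = np.empty((n_rec, n, 3), dtype=np.float32)
    ke = np.zeros(schedule.n_blocks)
    maxbond = np.zeros(schedule.n_blocks)
    disp = np.zeros(schedule.n_blocks)
    coll_prob = 1.0 - np.exp(
        -schedule.thermostat_collision_rate * schedule.timestep
    )
    conf_r = params.confinement_radius if params.confined else -1.0

    status, blk = _kernels.integrate_run(
        x, v,
        schedule.n_blocks, schedule.steps_per_block,
        schedule.timestep, schedule.friction, coll_prob,
        loop_a, loop_b,
        params.bond_k, params.stiffness_k, params.e_cutoff,
        params.crossing_allowed, params.phantom,
        conf_r, params.confinement_slope,
        -1.0,  # no force cap in production dynamics
        excl, int(seed) % 2**31,
        schedule.equilibration_blocks,
        rec, ke, maxbond, disp,
    )
    if status == _kernels.BLOWUP:
        raise BlowUpError(
            f"non-finite coordinates in block {blk}; try a smaller timestep"
        )
    if status == _kernels.PAIR_OVERFLOW:
        # a diverging system stretches bonds and scatters particles, which
        # also exhausts the neighbor grid: report that as a blow-up
        bonds = np.linalg.norm(np.roll(x, -1, axis=0) - x, axis=1)
        if not np.all(np.isfinite(x)) or bonds.max() > 5.0:
            raise BlowUpError(
                f"coordinates diverged by block {blk}; try a smaller timestep"
            )
        raise RuntimeError(f"neighbor-list capacity exceeded in block {blk}")

    return Ensemble(
        coords=rec,
        block_indices=np.arange(schedule.equilibration_blocks, schedule.n_blocks),
        params=params,
        schedule=schedule,
        seed=seed,
        diagnostics={
            "kinetic_energy": ke,
            "max_bond": maxbond,
            "mean_displacement": disp,
        },
    )


def equilibration_check(
    mean_displacement: np.ndarray,
    window: int = 50,
    rel_change: float = 0.02,
) -> int:
    """First block after which the displacement signal has saturated.

    The per-block mean monomer displacement from the start is averaged over
    consecutive ``window``-block windows; saturation is the first window from
    which every subsequent window-to-window change is below ``rel_change``.
    Returns the corresponding block index, or :data:`NOT_SATURATED` (with a
    warning) if the signal keeps growing.
    """
    sig = np.asarray(mean_displacement, dtype=float)
    if sig.size < 2 * window:
        raise ValueError(f"need at least {2 * window} recorded blocks")
    n_win = sig.size // window
    w = sig[: n_win * window].reshape(n_win, window).mean(axis=1)
    scale = np.maximum(np.abs(w[1:]), 1e-300)
    ok = np.abs(np.diff(w)) / scale < rel_change
    # first window index t such that all subsequent transitions are quiet
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return 0
    t = bad[-1] + 1
    if t >= n_win - 1:
        warnings.warn("displacement signal did not saturate", stacklevel=2)
        return NOT_SATURATED
    return int(t * window)


@dataclass
class TimestepReport:
    """Outcome of the timestep validation procedure."""

    timestep: float
    ke_drift: float
    ke_drift_threshold: float
    ke_ok: bool
    knot_checked: bool
    knot_conserved: bool
    passed: bool


def validate_timestep(
    params: SimulationParameters,
    schedule: SamplingSchedule,
    seed: int = 0,
    drift_threshold: float = 0.02,
) -> TimestepReport:
    """Check the timestep: kinetic-energy conservation and no fiber crossing.

    A thermostat-free (NVE) stretch after a thermostatted warm-up must show a
    relative kinetic-energy drift below ``drift_threshold``; additionally, a
    short non-crossing run of a small dense ring must conserve the Alexander
    knot determinant (skipped for phantom chains, which have nothing to
    cross).
    """
    from .initialize import prepare_start
    from .topology import alexander_determinant

    # --- kinetic-energy drift, thermostat off ---
    small = replace(
        params,
        n_monomers=min(params.n_monomers, 400),
        loops=[],
    )
    start = prepare_start(small, seed=seed)
    try:
        warm = SamplingSchedule(
            n_blocks=40, steps_per_block=200, equilibration_blocks=39,
            timestep=schedule.timestep, friction=1.0,
            thermostat_collision_rate=schedule.thermostat_collision_rate,
        )
        ens = run_dynamics(start, small, warm, seed=seed + 1)
        nve = SamplingSchedule(
            n_blocks=60, steps_per_block=200, equilibration_blocks=59,
            timestep=schedule.timestep, friction=0.0,
            thermostat_collision_rate=0.0,
        )
        ens2 = run_dynamics(ens.conformation(-1), small, nve, seed=seed + 2)
        ke = ens2.diagnostics["kinetic_energy"]
        third = len(ke) // 3
        head = ke[:third].mean()
        tail = ke[-third:].mean()
        drift = abs(tail - head) / max(head, 1e-12)
    except BlowUpError:
        drift = float("inf")
    ke_ok = drift < drift_threshold

    # --- knot-invariant conservation with the non-truncated potential ---
    knot_checked = not params.phantom
    knot_conserved = True
    if knot_checked:
        dense = replace(
            params,
            n_monomers=200,
            volume_density=0.2,
            crossing_allowed=False,
            phantom=False,
            loops=[],
        )
        dstart = prepare_start(dense, seed=seed + 3)
        dsched = SamplingSchedule(
            n_blocks=40, steps_per_block=500, equilibration_blocks=0,
            timestep=schedule.timestep, friction=schedule.friction,
            thermostat_collision_rate=schedule.thermostat_collision_rate,
        )
        try:
            dens = run_dynamics(dstart, dense, dsched, seed=seed + 4)
            ref = alexander_determinant(dstart, seed=seed)
            for i in range(0, dens.n_conformations, 5):
                if alexander_determinant(dens.conformation(i), seed=seed) != ref:
                    knot_conserved = False
                    break
        except BlowUpError:
            knot_conserved = False

    return TimestepReport(
        timestep=schedule.timestep,
        ke_drift=float(drift),
        ke_drift_threshold=drift_threshold,
        ke_ok=bool(ke_ok),
        knot_checked=knot_checked,
        knot_conserved=bool(knot_conserved),
        passed=bool(ke_ok and knot_conserved),
    )
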