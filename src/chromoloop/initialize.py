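"""Unentangled starting conformations.

Closed rings are grown on a cubic lattice by kink insertion: starting from a
4-monomer square, a random bond is shifted by one lattice unit in a random
perpendicular direction, and if both shifted sites are free the bond is
expanded into a kink, adding two monomers.  No strand can pass between the
old bond and the kink, so every intermediate ring is an unknot.

The grown ring is then cast to continuous coordinates and, if it does not fit
inside the confinement sphere, pre-compacted by short non-crossing dynamics
under a shrinking confinement radius (excluded volume on, crossing off, so
the topology is preserved).  ``prepare_start`` additionally closes any
permanent loops gently (force-capped relaxation) before production dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import Conformation, SimulationParameters

__all__ = ["LatticeRing", "grow_unentangled_ring", "lattice_to_offlattice", "prepare_start"]

#: the 4 unit steps perpendicular to each axis direction
_PERP = {
    0: [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    1: [(1, 0, 0), (-1, 0, 0), (0, 0, 1), (0, 0, -1)],
    2: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)],
}


@dataclass
class LatticeRing:
    """Self-avoiding closed ring on the cubic lattice."""

    sites: np.ndarray  # (N, 3) int

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        n = self.sites.shape[0]
        if n % 2:
            raise ValueError("lattice ring must have an even number of sites")
        steps = np.roll(self.sites, -1, axis=0) - self.sites
        if not np.all(np.abs(steps).sum(axis=1) == 1):
            raise ValueError("consecutive sites must differ by one unit step")
        if len({tuple(s) for s in self.sites}) != n:
            raise ValueError("ring is not self-avoiding")

    @property
    def n_monomers(self) -> int:
        return self.sites.shape[0]

    def to_xyz(self, path) -> None:
        write_xyz(path, self.sites.astype(float))


def write_xyz(path, coords: np.ndarray, comment: str = "chromoloop ring") -> None:
    """Write one conformation in plain XYZ format."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{coords.shape[0]}\n{comment}\n")
        for x, y, z in coords:
            fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> np.ndarray:
    """Read one conformation from an XYZ file."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        coords = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            coords[i] = [float(v) for v in parts[-3:]]
    return coords


def grow_unentangled_ring(
    n_monomers: int, seed: int, max_retries_per_step: int = 10**6
) -> LatticeRing:
    """Grow a self-avoiding, provably unknotted lattice ring by kink moves.

    Starts from a unit square and repeatedly extends a randomly chosen bond
    into a kink in one of the 4 perpendicular directions, rejecting moves
    whose target sites are occupied, until the ring has ``n_monomers`` sites.
    """
    if n_monomers < 4 or n_monomers % 2:
        raise ValueError("n_monomers must be even and >= 4")
    rng = np.random.default_rng(seed)
    ring = [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)]
    occupied = set(ring)
    while len(ring) < n_monomers:
        for attempt in range(max_retries_per_step):
            m = len(ring)
            ib = int(rng.integers(m))
            a = ring[ib]
            b = ring[(ib + 1) % m]
            axis = int(np.argmax(np.abs(np.subtract(b, a))))
            p = _PERP[axis][int(rng.integers(4))]
            q1 = (a[0] + p[0], a[1] + p[1], a[2] + p[2])
            q2 = (b[0] + p[0], b[1] + p[1], b[2] + p[2])
            if q1 not in occupied and q2 not in occupied:
                ring[ib + 1 : ib + 1] = [q1, q2]
                occupied.add(q1)
                occupied.add(q2)
                break
        else:
            raise RuntimeError(
                f"ring growth stalled at {len(ring)} monomers "
                f"after {max_retries_per_step} rejected moves"
            )
    return LatticeRing(np.array(ring))


def _relax(
    coords: np.ndarray,
    params: SimulationParameters,
    n_steps: int,
    seed: int,
    conf_r: float,
    dt: float = 0.02,
    force_cap: float = 100.0,
    with_loops: bool = False,
) -> np.ndarray:
    """Short capped-force, non-crossing relaxation used during preparation."""
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    x = np.ascontiguousarray(coords, dtype=np.float64)
    pairs = params.loop_pairs() if with_loops else np.empty((0, 2), dtype=np.int64)
    nb = max(1, n_steps // 500)
    rec = np.empty((1, n, 3), dtype=np.float32)
    ke = np.empty(nb)
    mb = np.empty(nb)
    dp = np.empty(nb)
    status, blk = _kernels.integrate_run(
        x, v, nb, 500, dt, 0.5, 0.0,
        np.ascontiguousarray(pairs[:, 0]) if len(pairs) else np.empty(0, dtype=np.int64),
        np.ascontiguousarray(pairs[:, 1]) if len(pairs) else np.empty(0, dtype=np.int64),
        params.bond_k, params.stiffness_k, params.e_cutoff,
        False, False, conf_r, params.confinement_slope,
        force_cap, np.empty(0, dtype=np.int64), seed % 2**31,
        nb - 1, rec, ke, mb, dp,
    )
    if status != _kernels.OK:
        raise RuntimeError(f"pre-compaction dynamics failed in block {blk}")
    return x


def lattice_to_offlattice(
    ring: LatticeRing, params: SimulationParameters, seed: int = 0
) -> Conformation:
    """Cast a lattice ring to continuous coordinates inside the confinement.

    The ring is recentred; if its extent exceeds the confinement radius it is
    isotropically pre-compacted by short non-crossing dynamics under a
    stepwise-shrinking confinement radius, preserving the unknotted topology.
    """
    x = ring.sites.astype(np.float64)
    x -= x.mean(axis=0)
    if not params.confined:
        return Conformation(x)
    target = params.confinement_radius
    extent = float(np.linalg.norm(x, axis=1).max())
    if extent <= target:
        return Conformation(x)
    r = extent
    stage = 0
    while r > target:
        r = max(target, 0.85 * r)
        x = _relax(x, params, 1500, seed * 9973 + stage + 1, r)
        stage += 1
    # settle at the final radius until everything is inside
    for extra in range(20):
        if np.linalg.norm(x, axis=1).max() <= target + 1.0:
            break
        x = _relax(x, params, 1000, seed * 9973 + 500 + extra, target)
    return Conformation(x)


def _phantom_premix(
    x: np.ndarray,
    params: SimulationParameters,
    seed: int,
    t_mix: float,
    dt: float = 0.05,
    collision_rate: float = 0.2,
) -> np.ndarray:
    """Mix the large-scale fold cheaply with phantom-mode dynamics.

    Without excluded volume the ring's global conformation relaxes orders of
    magnitude faster (and tolerates a larger timestep, having no steep core),
    so a short phantom stretch replaces an unaffordably long wait for the
    confined ring to forget its compact lattice origin.  Bonds, bending,
    loops and confinement stay on.  Only used for scenarios that may cross
    (topo-II active or phantom production), where the topological state is
    free to change anyway; non-crossing scenarios keep the certified
    unknotted lattice start.
    """
    n = params.n_monomers
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    x = np.ascontiguousarray(x, dtype=np.float64)
    loops = params.loop_pairs()
    la = np.ascontiguousarray(loops[:, 0]) if len(loops) else np.empty(0, np.int64)
    lb = np.ascontiguousarray(loops[:, 1]) if len(loops) else np.empty(0, np.int64)
    n_steps = max(1, int(t_mix / dt))
    nb = 10
    rec = np.empty((1, n, 3), dtype=np.float32)
    ke = np.empty(nb)
    mb = np.empty(nb)
    dp = np.empty(nb)
    conf_r = params.confinement_radius if params.confined else -1.0
    status, blk = _kernels.integrate_run(
        x, v, nb, n_steps // nb, dt, 0.0,
        1.0 - np.exp(-collision_rate * dt),
        la, lb, params.bond_k, params.stiffness_k, params.e_cutoff,
        True, True, conf_r, params.confinement_slope, -1.0,
        np.empty(0, dtype=np.int64), seed % 2**31,
        nb - 1, rec, ke, mb, dp,
    )
    if status != _kernels.OK:
        raise RuntimeError(f"phantom premix failed in block {blk}")
    return x


def prepare_start(
    params: SimulationParameters, seed: int = 0, premix_time: float | None = None
) -> Conformation:
    """Grow, confine, close loop bonds, and (for crossable scenarios) mix.

    Loop closure uses capped forces so that the initially distant anchors are
    pulled together without destabilising the integrator; production dynamics
    then starts from an already-closed loop, as the equilibration discard
    assumes.  When the scenario allows strand crossing (or is phantom), the
    start is additionally pre-mixed by phantom dynamics (``premix_time``
    reduced time units, default 40000; pass 0 to disable) so that production
    runs begin from an independent, well-mixed global fold; for non-crossing
    scenarios no premix is applied and the certified unknotted lattice
    topology is kept.
    """
    if premix_time is None:
        premix_time = 40_000.0 if (params.crossing_allowed or params.phantom) else 0.0
        if params.phantom:
            premix_time = 20_000.0
    ring = grow_unentangled_ring(params.n_monomers, seed)
    conf = lattice_to_offlattice(ring, params, seed=seed)
    if not params.loops and premix_time <= 0:
        return conf
    if not params.loops:
        return Conformation(
            _phantom_premix(conf.coords, params, seed * 613 + 11, premix_time)
        )
    x = conf.coords
    conf_r = params.confinement_radius if params.confined else -1.0
    for stage in range(60):
        dists = [
            np.linalg.norm(x[lp.anchor_a] - x[lp.anchor_b]) for lp in params.loops
        ]
        if max(dists) < 2.0:
            break
        x = _relax(
            x, params, 1500, seed * 31337 + stage + 7, conf_r,
            force_cap=80.0, with_loops=True,
        )
    else:
        raise RuntimeError("loop closure did not converge")
    # short uncapped settle with loops bonded
    x = _relax(
        x, params, 1000, seed * 31337 + 9999, conf_r,
        force_cap=-1.0, with_loops=True,
    )
    if premix_time > 0:
        x = _phantom_premix(x, params, seed * 613 + 11, premix_time)
    return Conformation(x)
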