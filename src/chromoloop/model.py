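"""Domain types and potential-energy terms for the chromatin-loop polymer model.

The chromatin fiber is a closed bead-spring ring in reduced units
(monomer diameter d = 1, thermal energy kT = 1, monomer mass m = 1).
Each monomer represents ``bp_per_monomer`` basepairs of chromatin
(default 500 bp, about three nucleosomes, a 15 nm bead).

Energy terms (all in kT):

* backbone / loop bonds:  U = 25 (r - 1)^2
* bending stiffness:      U = k (1 - cos a),  a = angle between successive bonds
* excluded volume:        shifted, purely repulsive Lennard-Jones
                          U = 4 (r^-12 - r^-6) + 1 for r < 2^(1/6), else 0,
                          with the interaction radius floored via
                          r_t = (r^10 + 0.3^10)^(1/10) and, when fiber
                          crossing is allowed (topo-II active), softened above
                          E_cutoff/2 as U_s = (E_cutoff/2)(1 + tanh(2U/E_cutoff - 1))
                          so the pair energy is capped at E_cutoff
* spherical confinement:  U = slope * max(0, |x| - R) per monomer, imposing a
                          target volume density inside radius R.

``total_energy_forces`` is a straightforward vectorised reference
implementation with analytic forces; the production integrator uses the
compiled kernels in :mod:`chromoloop._kernels`, which are tested against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "LJ_CUTOFF",
    "R_FLOOR",
    "LoopSpec",
    "SimulationParameters",
    "Conformation",
    "bond_energy",
    "angle_energy",
    "repulsive_energy",
    "confinement_radius",
    "total_energy_forces",
]

#: repulsion range: the shifted LJ potential vanishes beyond 2^(1/6) diameters
LJ_CUTOFF: float = 2.0 ** (1.0 / 6.0)

#: interaction-radius floor protecting against the r -> 0 singularity
R_FLOOR: float = 0.3

#: densities above ~1.41 monomers per cubic diameter exceed sphere close
#: packing (volume fraction 0.74)
_PHI_MAX = 1.41


@dataclass(frozen=True)
class LoopSpec:
    """A permanent chromatin loop: a harmonic bond joining two monomers."""

    anchor_a: int
    anchor_b: int

    def __post_init__(self) -> None:
        if self.anchor_a == self.anchor_b:
            raise ValueError("loop anchors must be distinct monomers")

    def length(self, n_monomers: int) -> int:
        """Genomic loop length in monomers (shorter ring distance)."""
        d = abs(self.anchor_b - self.anchor_a)
        return min(d, n_monomers - d)

    def interior(self, n_monomers: int) -> np.ndarray:
        """Indices strictly inside the loop (anchors excluded), along the
        shorter ring arc, ordered from anchor_a towards anchor_b."""
        a, b = self.anchor_a, self.anchor_b
        d = (b - a) % n_monomers
        if d <= n_monomers - d:
            return np.array([(a + i) % n_monomers for i in range(1, d)])
        d = (a - b) % n_monomers
        return np.array([(b + i) % n_monomers for i in range(1, d)])[::-1]


@dataclass
class SimulationParameters:
    """All physical constants of one simulation scenario (reduced units).

    Genomic / physical metadata (``bp_per_monomer``, ``monomer_diameter_nm``)
    is used only for reporting; the dynamics runs in reduced units.
    """

    n_monomers: int
    bp_per_monomer: int = 500
    monomer_diameter_nm: float = 15.0
    stiffness_k: float = 3.0
    e_cutoff: float = 3.0
    crossing_allowed: bool = True
    phantom: bool = False
    volume_density: float = 0.02
    bond_k: float = 25.0
    confinement_slope: float = 5.0
    confined: bool = True
    exclude_loop_anchor_repulsion: bool = False
    loops: list[LoopSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 4 or self.n_monomers % 2:
            raise ValueError("n_monomers must be even and >= 4")
        if not 0.0 < self.volume_density < _PHI_MAX:
            raise ValueError(f"volume_density must be in (0, {_PHI_MAX})")
        if self.stiffness_k < 0:
            raise ValueError("stiffness_k must be >= 0")
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be > 0")
        loops = []
        for lp in self.loops:
            if not isinstance(lp, LoopSpec):
                lp = LoopSpec(*lp) if not isinstance(lp, dict) else LoopSpec(**lp)
            for anchor in (lp.anchor_a, lp.anchor_b):
                if not 0 <= anchor < self.n_monomers:
                    raise ValueError(f"loop anchor {anchor} outside ring")
            loops.append(lp)
        self.loops = loops

    @property
    def confinement_radius(self) -> float:
        return confinement_radius(self.n_monomers, self.volume_density)

    def loop_pairs(self) -> np.ndarray:
        """(n_loops, 2) int array of anchor pairs (empty-safe)."""
        if not self.loops:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([[lp.anchor_a, lp.anchor_b] for lp in self.loops])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loops"] = [[lp.anchor_a, lp.anchor_b] for lp in self.loops]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d["loops"] = [LoopSpec(int(a), int(b)) for a, b in d.get("loops", [])]
        return cls(**d)


@dataclass
class Conformation:
    """One snapshot of the ring: N coordinate triples in monomer diameters."""

    coords: np.ndarray
    is_ring: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        """Lengths of the N ring bonds (diagnostic)."""
        d = np.roll(self.coords, -1, axis=0) - self.coords
        return np.linalg.norm(d, axis=1)


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

def bond_energy(r, bond_k: float = 25.0):
    """Harmonic bond energy U = bond_k (r - 1)^2, rest length one diameter."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    return bond_k * (r - 1.0) ** 2


def angle_energy(alpha, k: float):
    """Bending energy U = k (1 - cos alpha) for the angle between bonds."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha < 0) | (alpha > np.pi)):
        raise ValueError("alpha must lie in [0, pi]")
    return k * (1.0 - np.cos(alpha))


def _lj_raw(rt):
    """Shifted purely-repulsive LJ at (already floored) radius rt."""
    inv6 = rt ** -6.0
    return np.where(rt < LJ_CUTOFF, 4.0 * (inv6 * inv6 - inv6) + 1.0, 0.0)


def repulsive_energy(
    r,
    e_cutoff: float = 3.0,
    crossing_allowed: bool = True,
    phantom: bool = False,
):
    """Excluded-volume pair energy at distance ``r``.

    With ``crossing_allowed`` the energy is softened above ``e_cutoff``/2 and
    capped at ``e_cutoff`` (occasional strand passage, topo-II active); without
    it, the full shifted LJ applies and fibers cannot cross.  A ``phantom``
    chain has no excluded volume at all.
    """
    r = np.asarray(r, dtype=float)
    if phantom:
        return np.zeros_like(r)
    rt = (r ** 10.0 + R_FLOOR ** 10.0) ** 0.1
    u = _lj_raw(rt)
    if crossing_allowed:
        half = 0.5 * e_cutoff
        u = np.where(u > half, half * (1.0 + np.tanh(2.0 * u / e_cutoff - 1.0)), u)
    return u[()] if u.ndim == 0 else u


def confinement_radius(n_monomers: int, volume_density: float) -> float:
    """Radius R of the confining sphere for a target density.

    The density parameter counts monomers per cubic monomer diameter:
    N / ((4/3) pi R^3) = phi, hence R = (3 N / (4 pi phi))^(1/3) for d = 1
    (so phi = 0.02 corresponds to a sphere volume fraction of
    0.02 * pi/6 ~ 1%).  This is the convention under which the reference
    dense-system checks (density 0.85, far above the 0.74 volume-fraction
    ceiling for spheres) are meaningful.
    """
    if not 0.0 < volume_density < _PHI_MAX:
        raise ValueError(f"volume_density must be in (0, {_PHI_MAX})")
    return (3.0 * n_monomers / (4.0 * np.pi * volume_density)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# reference total energy / forces (vectorised numpy; oracle for the kernels)
# ---------------------------------------------------------------------------

def total_energy_forces(
    conf: Conformation, params: SimulationParameters
) -> tuple[float, np.ndarray]:
    """Total potential energy (kT) and exact analytic forces (-gradient).

    Terms: ring + loop harmonic bonds, three-point bending, pairwise
    excluded volume (ring-adjacent pairs excluded; loop-anchor pairs keep
    their repulsion unless ``exclude_loop_anchor_repulsion``), and linear
    spherical confinement.  O(N^2) in the pair term — intended as the
    trusted reference; production dynamics uses the compiled kernels.
    """
    x = np.asarray(conf.coords, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    n = x.shape[0]
    forces = np.zeros_like(x)
    energy = 0.0

    # bonds: ring-consecutive plus loop anchors
    pairs = [((i + 1) % n, i) for i in range(n)]
    pairs += [(lp.anchor_a, lp.anchor_b) for lp in params.loops]
    for a, b in pairs:
        dvec = x[a] - x[b]
        r = np.linalg.norm(dvec)
        energy += params.bond_k * (r - 1.0) ** 2
        if r > 0:
            f = -2.0 * params.bond_k * (r - 1.0) * dvec / r
            forces[a] += f
            forces[b] -= f

    # bending: angle at each monomer between its two adjacent bonds
    k = params.stiffness_k
    if k != 0.0:
        prev = np.roll(np.arange(n), 1)
        nxt = np.roll(np.arange(n), -1)
        u = x - x[prev]
        v = x[nxt] - x
        lu = np.linalg.norm(u, axis=1)
        lv = np.linalg.norm(v, axis=1)
        c = np.einsum("ij,ij->i", u, v) / (lu * lv)
        c = np.clip(c, -1.0, 1.0)
        energy += k * np.sum(1.0 - c)
        # dU/du and dU/dv with U = k (1 - cos a), cos a = u.v/(|u||v|)
        dc_du = v / (lu * lv)[:, None] - (c / lu**2)[:, None] * u
        dc_dv = u / (lu * lv)[:, None] - (c / lv**2)[:, None] * v
        g_u = -k * dc_du
        g_v = -k * dc_dv
        # u_i = x_i - x_{i-1}; v_i = x_{i+1} - x_i
        np.add.at(forces, np.arange(n), -(g_u - g_v))
        np.add.at(forces, prev, g_u)
        np.add.at(forces, nxt, -g_v)

    # excluded volume
    if not params.phantom:
        ii, jj = np.triu_indices(n, k=1)
        ring_sep = np.minimum(jj - ii, n - (jj - ii))
        keep = ring_sep >= 2
        if params.exclude_loop_anchor_repulsion:
            for lp in params.loops:
                a, b = sorted((lp.anchor_a, lp.anchor_b))
                keep &= ~((ii == a) & (jj == b))
        ii, jj = ii[keep], jj[keep]
        dvec = x[ii] - x[jj]
        r = np.linalg.norm(dvec, axis=1)
        rt = (r**10 + R_FLOOR**10) ** 0.1
        act = rt < LJ_CUTOFF
        if np.any(act):
            ii, jj, dvec, r, rt = ii[act], jj[act], dvec[act], r[act], rt[act]
            inv6 = rt**-6
            u_raw = 4.0 * (inv6 * inv6 - inv6) + 1.0
            du_drt = 4.0 * (-12.0 * rt**-13 + 6.0 * rt**-7)
            if params.crossing_allowed:
                half = 0.5 * params.e_cutoff
                soft = u_raw > half
                uu = np.where(
                    soft,
                    half * (1.0 + np.tanh(2.0 * u_raw / params.e_cutoff - 1.0)),
                    u_raw,
                )
                arg = np.minimum(2.0 * u_raw / params.e_cutoff - 1.0, 350.0)
                sech2 = 1.0 / np.cosh(arg) ** 2
                du_drt = np.where(soft, sech2 * du_drt, du_drt)
            else:
                uu = u_raw
            energy += float(np.sum(uu))
            drt_dr = np.where(r > 0, (r / rt) ** 9, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                fmag = np.where(r > 0, -du_drt * drt_dr / r, 0.0)
            fvec = fmag[:, None] * dvec
            np.add.at(forces, ii, fvec)
            np.add.at(forces, jj, -fvec)

    # spherical confinement
    if params.confined:
        R = params.confinement_radius
        rad = np.linalg.norm(x, axis=1)
        out = rad > R
        if np.any(out):
            energy += params.confinement_slope * float(np.sum(rad[out] - R))
            forces[out] -= (
                params.confinement_slope * x[out] / rad[out][:, None]
            )

    return float(energy), forces
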