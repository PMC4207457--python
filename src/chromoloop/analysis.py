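"""Ensemble statistics: contact maps, contact-frequency ratios, profiles,
radial density around a loop, and simulated FISH distance distributions.

The central readout is the *contact frequency ratio*: the contact frequency
of a locus pair in the looped ensemble divided by the frequency of the same
pair in a matched loop-free ensemble.  Ratios below 1 indicate insulation,
above 1 facilitation.  Frequencies are counts normalised by each ensemble's
conformation number, so ensembles of different depth are commensurable.

A contact is two monomers closer than 2 monomer diameters (strict
inequality).  Pairs closer than ``min_sep`` = 2 along the ring are excluded
from maps: at the 2.0 cutoff nearest neighbours are trivially always in
contact.  Every report echoes the window definitions used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .dynamics import Ensemble
from .model import Conformation, LoopSpec

__all__ = [
    "ContactMap",
    "RatioReport",
    "RadialDensityProfile",
    "FishDistribution",
    "LoopBaseProfile",
    "contacts",
    "ensemble_heatmap",
    "insulation_score",
    "facilitation_score",
    "intra_loop_score",
    "loop_base_profile",
    "radial_density",
    "fish_distances",
    "insulation_pair",
    "facilitation_pair",
    "control_pair",
    "two_loop_summary",
]

CONTACT_CUTOFF = 2.0
MIN_SEPARATION = 2


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Accumulated contact counts over an ensemble (symmetric, N x N)."""

    counts: np.ndarray
    n_conformations: int
    cutoff: float = CONTACT_CUTOFF
    min_sep: int = MIN_SEPARATION

    @property
    def n_monomers(self) -> int:
        return self.counts.shape[0]

    def frequency(self) -> np.ndarray:
        """Per-conformation contact frequency matrix."""
        return self.counts / float(self.n_conformations)

    def to_tsv(self, path) -> None:
        header = (
            f"# chromoloop contact map: n_conformations={self.n_conformations} "
            f"cutoff={self.cutoff} min_sep={self.min_sep}"
        )
        np.savetxt(path, self.counts, fmt="%d", delimiter="\t", header=header)

    @classmethod
    def from_tsv(cls, path) -> "ContactMap":
        with open(path) as fh:
            head = fh.readline()
        meta = dict(
            kv.split("=") for kv in head.lstrip("# ").split(":", 1)[1].split()
        )
        counts = np.loadtxt(path, dtype=np.int64, delimiter="\t")
        return cls(
            counts=counts,
            n_conformations=int(meta["n_conformations"]),
            cutoff=float(meta["cutoff"]),
            min_sep=int(meta["min_sep"]),
        )

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            counts=self.counts,
            n_conformations=self.n_conformations,
            cutoff=self.cutoff,
            min_sep=self.min_sep,
        )

    @classmethod
    def from_npz(cls, path) -> "ContactMap":
        z = np.load(path)
        return cls(
            counts=z["counts"],
            n_conformations=int(z["n_conformations"]),
            cutoff=float(z["cutoff"]),
            min_sep=int(z["min_sep"]),
        )


def contacts(
    conf: Conformation,
    cutoff: float = CONTACT_CUTOFF,
    min_sep: int = MIN_SEPARATION,
) -> set[tuple[int, int]]:
    """Unordered monomer pairs at Euclidean distance strictly below ``cutoff``
    with ring separation >= ``min_sep``."""
    x = np.ascontiguousarray(conf.coords, dtype=np.float64)
    cap = 64 * x.shape[0]
    while True:
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        cnt = _kernels.contact_pairs_kernel(x, cutoff, min_sep, pi, pj)
        if cnt == -2:
            raise ValueError("conformation extent exceeds the contact grid")
        if cnt >= 0:
            return {(int(pi[k]), int(pj[k])) for k in range(cnt)}
        cap *= 2


def _as_coord_blocks(ensemble) -> np.ndarray:
    if isinstance(ensemble, Ensemble):
        return ensemble.coords
    if isinstance(ensemble, Conformation):
        return ensemble.coords[None].astype(np.float32)
    arr = np.asarray(ensemble)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float32, copy=False)


def ensemble_heatmap(
    ensemble,
    cutoff: float = CONTACT_CUTOFF,
    min_sep: int = MIN_SEPARATION,
) -> ContactMap:
    """Accumulate per-conformation contact sets into a symmetric heatmap.

    Accepts an :class:`Ensemble`, a list of ensembles (pooled), or a raw
    (M, N, 3) coordinate array.
    """
    if isinstance(ensemble, (list, tuple)):
        blocks_list = [_as_coord_blocks(e) for e in ensemble]
    else:
        blocks_list = [_as_coord_blocks(ensemble)]
    n = blocks_list[0].shape[1]
    if any(b.shape[1] != n for b in blocks_list):
        raise ValueError("ensembles have mismatched monomer counts")
    counts = np.zeros((n, n), dtype=np.int64)
    total = 0
    for blocks in blocks_list:
        if blocks.shape[0] == 0:
            raise ValueError("empty ensemble")
        _kernels.accumulate_contact_map(
            np.ascontiguousarray(blocks, dtype=np.float32), cutoff, min_sep, counts
        )
        total += blocks.shape[0]
    return ContactMap(counts=counts, n_conformations=total,
                      cutoff=cutoff, min_sep=min_sep)


# ---------------------------------------------------------------------------
# contact-frequency ratios
# ---------------------------------------------------------------------------

@dataclass
class RatioReport:
    """A contact-frequency ratio with its averaging-window definition.

    ``stderr`` is the standard deviation of per-run ratios across the
    independent looped runs (each against the pooled no-loop frequency),
    matching error bars of one standard deviation about the mean.
    """

    arrangement: str
    ep_distance: int
    loop_length: int
    ratio: float
    stderr: float
    n_pairs: int
    window: dict = field(default_factory=dict)
    run_ratios: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _as_map_list(maps) -> list[ContactMap]:
    if isinstance(maps, ContactMap):
        return [maps]
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one contact map")
    return maps


def _window_frequency(maps: list[ContactMap], pairs: np.ndarray) -> float:
    """Mean per-conformation contact frequency over the window pairs, with
    counts pooled across maps."""
    tot_conf = sum(m.n_conformations for m in maps)
    s = 0.0
    for m in maps:
        s += m.counts[pairs[:, 0], pairs[:, 1]].sum()
    return s / (tot_conf * len(pairs))


def _window_counts(maps: list[ContactMap], pairs: np.ndarray) -> int:
    return int(sum(m.counts[pairs[:, 0], pairs[:, 1]].sum() for m in maps))


def _ring_averaged_frequency(
    maps: list[ContactMap], pairs: np.ndarray
) -> tuple[float, int]:
    """Mean frequency over the window cells with each cell's value replaced
    by the ring average at that cell's separation (valid for the loop-free
    ring, which is statistically translation invariant)."""
    n = maps[0].n_monomers
    tot_conf = sum(m.n_conformations for m in maps)
    counts = sum(m.counts for m in maps)
    idx = np.arange(n)
    seps = np.minimum((pairs[:, 1] - pairs[:, 0]) % n, (pairs[:, 0] - pairs[:, 1]) % n)
    ring_p = {}
    ring_c = 0
    for d in np.unique(seps):
        c = int(counts[idx, (idx + d) % n].sum())
        ring_p[int(d)] = c / (tot_conf * n)
        ring_c += c
    freq = float(np.mean([ring_p[int(d)] for d in seps]))
    return freq, ring_c


def _ratio_with_spread(
    loop_maps: list[ContactMap],
    noloop_maps: list[ContactMap],
    pairs: np.ndarray,
    noloop_estimator: str = "window",
) -> tuple[float, float, list[float], dict]:
    counts = {
        "loop_counts": _window_counts(loop_maps, pairs),
        "noloop_estimator": noloop_estimator,
    }
    if noloop_estimator == "window":
        denom = _window_frequency(noloop_maps, pairs)
        counts["noloop_counts"] = _window_counts(noloop_maps, pairs)
    elif noloop_estimator == "ring_average":
        denom, ring_c = _ring_averaged_frequency(noloop_maps, pairs)
        counts["noloop_counts"] = ring_c
    else:
        raise ValueError(f"unknown noloop_estimator {noloop_estimator!r}")
    num = _window_frequency(loop_maps, pairs)
    if denom == 0.0:
        return float("inf"), float("nan"), [], counts
    ratio = num / denom
    run_ratios = [
        _window_frequency([m], pairs) / denom for m in loop_maps
    ]
    spread = float(np.std(run_ratios, ddof=1)) if len(run_ratios) > 1 else float("nan")
    return float(ratio), spread, [float(r) for r in run_ratios], counts


def _check_same_n(loop_maps, noloop_maps) -> int:
    n = loop_maps[0].n_monomers
    for m in loop_maps + noloop_maps:
        if m.n_monomers != n:
            raise ValueError("contact maps have mismatched sizes")
    return n


def _anchors(loop: LoopSpec) -> tuple[int, int]:
    return min(loop.anchor_a, loop.anchor_b), max(loop.anchor_a, loop.anchor_b)


def _proximal_third(loop: LoopSpec, n: int) -> np.ndarray:
    """Intra-loop monomers in the promoter-proximal third, i.e. the third of
    the loop interior nearest the downstream (promoter-side) anchor; anchors
    themselves are excluded."""
    a, b = _anchors(loop)
    interior = np.arange(a + 1, b)
    third = max(1, len(interior) // 3)
    return interior[-third:]


def insulation_positions(loop: LoopSpec, n: int, enhancer="proximal_third") -> np.ndarray:
    """Enhancer positions for the insulation arrangement."""
    a, b = _anchors(loop)
    if isinstance(enhancer, str):
        if enhancer == "proximal_third":
            return _proximal_third(loop, n)
        if enhancer == "midpoint":
            return np.array([(a + b) // 2])
        if enhancer == "near_base":
            return np.array([b - 1])
        raise ValueError(f"unknown enhancer window {enhancer!r}")
    return np.atleast_1d(np.asarray(enhancer, dtype=int))


def insulation_score(
    loop_maps,
    noloop_maps,
    loop: LoopSpec,
    ep_distance: int,
    enhancer="proximal_third",
    sep_window: int = 3,
    orientation: str = "downstream",
    noloop_estimator: str = "window",
) -> RatioReport:
    """Contact-frequency ratio for the insulation arrangement.

    The enhancer lies inside the loop (by default averaged over the
    promoter-proximal third of the loop interior) and the promoter sits
    outside the loop at ``ep_distance`` monomers; the window additionally
    averages over a +/- ``sep_window`` monomer E-P separation.  Ratio < 1
    means the loop insulates the pair.

    ``orientation`` places the promoter "downstream" of the high anchor (the
    default), "upstream" of the low anchor with the mirrored enhancer window,
    or pools "both" orientations — the two are mirror images about the loop
    centre and estimate the same quantity, so pooling only reduces sampling
    noise.  ``noloop_estimator="ring_average"`` replaces the loop-free
    window frequency by the ring average at the same separations (the
    loop-free ring is translation invariant, so this estimates the same
    expectation with far less noise at reduced sampling depth).
    """
    loop_maps = _as_map_list(loop_maps)
    noloop_maps = _as_map_list(noloop_maps)
    n = _check_same_n(loop_maps, noloop_maps)
    a, b = _anchors(loop)
    enh = insulation_positions(loop, n, enhancer)
    if orientation not in ("downstream", "upstream", "both"):
        raise ValueError(f"unknown orientation {orientation!r}")
    pairs = []
    for e in enh:
        if not a < e < b:
            raise ValueError(f"enhancer {e} is not inside the loop ({a}, {b})")
        for s in range(ep_distance - sep_window, ep_distance + sep_window + 1):
            if orientation in ("downstream", "both"):
                p = e + s
                if p >= n:
                    raise ValueError("promoter window exits the chain")
                pairs.append((e, p))
            if orientation in ("upstream", "both"):
                # mirror the enhancer through the loop centre, promoter below
                e2 = a + b - e
                p2 = e2 - s
                if p2 < 0:
                    raise ValueError("promoter window exits the chain")
                pairs.append((p2, e2))
    pairs = np.array(pairs)
    ratio, spread, run_ratios, counts = _ratio_with_spread(
        loop_maps, noloop_maps, pairs, noloop_estimator
    )
    return RatioReport(
        arrangement="insulation",
        ep_distance=int(ep_distance),
        loop_length=loop.length(n),
        ratio=ratio,
        stderr=spread,
        n_pairs=len(pairs),
        window={
            "enhancer": str(enhancer),
            "enhancer_positions": [int(e) for e in enh],
            "separation_window": int(sep_window),
            "orientation": orientation,
            "min_sep_excluded_from_maps": loop_maps[0].min_sep,
            **counts,
        },
        run_ratios=run_ratios,
    )


def facilitation_score(
    loop_maps,
    noloop_maps,
    loop: LoopSpec,
    ep_distance: int,
    sep_window: int = 3,
    offset_window: int | None = None,
    noloop_estimator: str = "window",
) -> RatioReport:
    """Contact-frequency ratio for the facilitation arrangement.

    The E-P pair straddles the loop symmetrically around its centre; the
    window averages over +/- ``sep_window`` monomers of E-P separation and a
    +/- (ep_distance - loop_length)/6 monomer offset of the pair's midpoint
    from the loop centre.  Ratio > 1 means the loop facilitates the pair.
    """
    loop_maps = _as_map_list(loop_maps)
    noloop_maps = _as_map_list(noloop_maps)
    n = _check_same_n(loop_maps, noloop_maps)
    a, b = _anchors(loop)
    length = loop.length(n)
    if ep_distance <= length:
        raise ValueError(
            "facilitation needs ep_distance > loop length; "
            "use intra_loop_score for an intra-loop pair"
        )
    if offset_window is None:
        offset_window = int((ep_distance - length) / 6)
    c = 0.5 * (a + b)
    pairs = []
    for s in range(ep_distance - sep_window, ep_distance + sep_window + 1):
        lo = int(np.ceil(c - offset_window - 0.5 * s))
        hi = int(np.floor(c + offset_window - 0.5 * s))
        for i in range(lo, hi + 1):
            j = i + s
            if i < 0 or j >= n:
                raise ValueError("facilitation window exits the chain")
            pairs.append((i, j))
    pairs = np.array(pairs)
    ratio, spread, run_ratios, counts = _ratio_with_spread(
        loop_maps, noloop_maps, pairs, noloop_estimator
    )
    return RatioReport(
        arrangement="facilitation",
        ep_distance=int(ep_distance),
        loop_length=length,
        ratio=ratio,
        stderr=spread,
        n_pairs=len(pairs),
        window={
            "separation_window": int(sep_window),
            "offset_window": int(offset_window),
            "loop_center": c,
            "min_sep_excluded_from_maps": loop_maps[0].min_sep,
            **counts,
        },
        run_ratios=run_ratios,
    )


def intra_loop_score(
    loop_maps,
    noloop_maps,
    loop: LoopSpec,
    positions: tuple[int, int],
    noloop_estimator: str = "window",
) -> RatioReport:
    """Single-cell contact-frequency ratio for an E-P pair inside the loop
    (no window averaging; intra-loop distances are short and well sampled)."""
    loop_maps = _as_map_list(loop_maps)
    noloop_maps = _as_map_list(noloop_maps)
    n = _check_same_n(loop_maps, noloop_maps)
    a, b = _anchors(loop)
    e, p = positions
    for pos in (e, p):
        if not a <= pos <= b:
            raise ValueError(f"position {pos} is outside the loop [{a}, {b}]")
    pairs = np.array([[min(e, p), max(e, p)]])
    ratio, spread, run_ratios, counts = _ratio_with_spread(
        loop_maps, noloop_maps, pairs, noloop_estimator
    )
    return RatioReport(
        arrangement="intra-loop",
        ep_distance=abs(p - e),
        loop_length=loop.length(n),
        ratio=ratio,
        stderr=spread,
        n_pairs=1,
        window={"positions": [int(e), int(p)],
                "min_sep_excluded_from_maps": loop_maps[0].min_sep,
                **counts},
        run_ratios=run_ratios,
    )


@dataclass
class LoopBaseProfile:
    """Contact-frequency-ratio track of a loop base against all other loci."""

    base: int
    offsets: np.ndarray
    ratio: np.ndarray


def loop_base_profile(loop_map: ContactMap, noloop_map: ContactMap, base: int) -> LoopBaseProfile:
    """4C-like profile: ratio of the heatmap row at a loop base between the
    looped and no-loop maps, as a function of signed genomic offset."""
    n = _check_same_n([loop_map], [noloop_map])
    offsets = np.arange(-(n // 2) + 1, n // 2)
    idx = (base + offsets) % n
    fl = loop_map.frequency()[base, idx]
    fn = noloop_map.frequency()[base, idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fn > 0, fl / fn, np.nan)
    ratio[np.abs(offsets) < loop_map.min_sep] = np.nan
    return LoopBaseProfile(base=base, offsets=offsets, ratio=ratio)


# ---------------------------------------------------------------------------
# spatial density around the loop
# ---------------------------------------------------------------------------

@dataclass
class RadialDensityProfile:
    """Normalized spatial density of distal monomers around the loop COM."""

    bin_edges: np.ndarray
    density: np.ndarray
    control: np.ndarray
    raw: dict = field(default_factory=dict)


def _arc_indices(a: int, b: int, n: int) -> np.ndarray:
    """Monomer indices along the shorter arc from a to b, inclusive."""
    d = (b - a) % n
    if d <= n - d:
        return (a + np.arange(d + 1)) % n
    d = (a - b) % n
    return (b + np.arange(d + 1)) % n


def radial_density(
    ensembles: Sequence[Ensemble],
    loop: LoopSpec,
    bin_width: float = 0.5,
    exclusion: int = 20,
) -> RadialDensityProfile:
    """Normalized density of distal monomers vs distance from the loop COM.

    Distal monomers are those outside the loop and more than ``exclusion``
    monomers from either loop base.  The raw distance histogram is divided
    bin-wise by the same histogram computed against a shuffled COM — the loop
    COM of the same conformation index in the next run (cyclically) — which
    removes the radial-position dependence imposed by confinement.  The
    control repeats the procedure for a pseudo-loop diametrically opposite on
    the ring.
    """
    if len(ensembles) < 2:
        raise ValueError("the shuffled-COM normalization needs >= 2 runs")
    n = ensembles[0].n_monomers
    a, b = _anchors(loop)
    m = min(e.n_conformations for e in ensembles)
    coords = [e.coords[:m] for e in ensembles]

    loop_idx = _arc_indices(a, b, n)
    mask = np.zeros(n, dtype=bool)
    span = (b + exclusion) - (a - exclusion) - 1
    for t in range(span):
        mask[(a - exclusion + 1 + t) % n] = True
    distal = np.nonzero(~mask)[0]

    half = n // 2
    ctrl_loop_idx = (loop_idx + half) % n
    ctrl_distal = (distal + half) % n

    rmax = 0.0
    for c in coords:
        rmax = max(rmax, float(np.abs(c).max()))
    edges = np.arange(0.0, 2.0 * rmax * np.sqrt(3) + 2 * bin_width, bin_width)

    def _profile(lidx, didx):
        real = np.zeros(len(edges) - 1)
        shuf = np.zeros(len(edges) - 1)
        nruns = len(coords)
        for y in range(nruns):
            com = coords[y][:, lidx, :].mean(axis=1)  # (m, 3)
            com_other = coords[(y + 1) % nruns][:, lidx, :].mean(axis=1)
            for xi in range(m):
                d = np.linalg.norm(
                    coords[y][xi, didx, :] - com[xi], axis=1
                )
                real += np.histogram(d, bins=edges)[0]
                d2 = np.linalg.norm(
                    coords[y][xi, didx, :] - com_other[xi], axis=1
                )
                shuf += np.histogram(d2, bins=edges)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(shuf > 0, real / shuf, np.nan), real, shuf

    density, real, shuf = _profile(loop_idx, distal)
    control, creal, cshuf = _profile(ctrl_loop_idx, ctrl_distal)
    return RadialDensityProfile(
        bin_edges=edges,
        density=density,
        control=control,
        raw={"real": real, "shuffled": shuf,
             "control_real": creal, "control_shuffled": cshuf},
    )


# ---------------------------------------------------------------------------
# simulated FISH
# ---------------------------------------------------------------------------

@dataclass
class FishDistribution:
    """Distribution of spatial distances between two tagged loci."""

    i: int
    j: int
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    distances: np.ndarray

    def cumulative(self) -> np.ndarray:
        c = np.cumsum(self.counts).astype(float)
        return c / c[-1]


def fish_distances(
    ensemble, i: int, j: int, bin_width: float = 0.5
) -> FishDistribution:
    """Per-conformation spatial distance between monomers i and j, binned
    from 0 in steps of ``bin_width`` (in-silico FISH)."""
    if isinstance(ensemble, (list, tuple)):
        blocks = np.concatenate([_as_coord_blocks(e) for e in ensemble], axis=0)
    else:
        blocks = _as_coord_blocks(ensemble)
    d = np.linalg.norm(
        blocks[:, i, :].astype(np.float64) - blocks[:, j, :].astype(np.float64),
        axis=1,
    )
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return FishDistribution(
        i=int(i), j=int(j), bin_edges=edges, counts=counts,
        mean=float(d.mean()), distances=d,
    )


# ---------------------------------------------------------------------------
# arrangement placements (shared by FISH and reporting)
# ---------------------------------------------------------------------------

def insulation_pair(loop: LoopSpec, n: int, ep_distance: int) -> tuple[int, int]:
    """Representative insulation E-P pair: enhancer at the centre of the
    promoter-proximal third of the loop, promoter outside at ep_distance
    (ring indices wrap)."""
    enh = _proximal_third(loop, n)
    e = int(enh[len(enh) // 2])
    return e, (e + ep_distance) % n


def facilitation_pair(loop: LoopSpec, n: int, ep_distance: int) -> tuple[int, int]:
    """Facilitation E-P pair placed symmetrically around the loop centre."""
    a, b = _anchors(loop)
    c = (a + b) // 2
    e = (c - ep_distance // 2) % n
    return e, (e + ep_distance) % n


def control_pair(loop: LoopSpec, n: int, ep_distance: int) -> tuple[int, int]:
    """Loop-free control pair: same separation, centred diametrically
    opposite the loop on the ring."""
    a, b = _anchors(loop)
    c = ((a + b) // 2 + n // 2) % n
    e = (c - ep_distance // 2) % n
    return e, (e + ep_distance) % n


def render_heatmap(cmap: ContactMap, path, log_scale: bool = True,
                   region: tuple[int, int] | None = None) -> None:
    """Render a contact map to PNG (log10 of counts by default)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = cmap.counts.astype(float)
    if region is not None:
        lo, hi = region
        data = data[lo:hi, lo:hi]
    with np.errstate(divide="ignore"):
        shown = np.log10(data + 1.0) if log_scale else data
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(shown, cmap="viridis", origin="lower")
    fig.colorbar(im, ax=ax, label="log10(contacts + 1)" if log_scale else "contacts")
    ax.set_xlabel("monomer")
    ax.set_ylabel("monomer")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def two_loop_summary(loop_map: ContactMap, loops: Sequence[LoopSpec]) -> dict:
    """Mean intra-loop vs inter-loop contact frequency for a two-loop system."""
    if len(loops) != 2:
        raise ValueError("expects exactly two loops")
    n = loop_map.n_monomers
    freq = loop_map.frequency()
    ins = []
    for lp in loops:
        a, b = _anchors(lp)
        idx = np.arange(a + 1, b)
        sub = freq[np.ix_(idx, idx)]
        sep_ok = np.abs(np.subtract.outer(idx, idx)) >= loop_map.min_sep
        ins.append(float(sub[sep_ok].mean()))
    a1, b1 = _anchors(loops[0])
    a2, b2 = _anchors(loops[1])
    idx1 = np.arange(a1 + 1, b1)
    idx2 = np.arange(a2 + 1, b2)
    idx1 = idx1[~np.isin(idx1, idx2)]
    inter = float(freq[np.ix_(idx1, idx2)].mean())
    return {
        "intra_loop_mean_frequency": ins,
        "inter_loop_mean_frequency": inter,
        "intra_over_inter": float(np.mean(ins) / inter) if inter > 0 else float("inf"),
    }
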