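"""Isochrone decomposition and VT-circuit component annotation.

One reentry cycle is divided into eight uniformly spaced time windows
(isochrones).  The critical isthmus is the slow-conducting corridor the
circuit threads: conducting nodes in the mid-cycle isochrones that are
hemmed in by non-conducting tissue on two opposing sides and adjacent to
the reentry core.  Entrance/exit/outer-loop/common-pathway labels follow
the clinical annotation vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .induction import VTEpisode
from .tissue import TissueDomain

__all__ = [
    "IsochroneMap",
    "CircuitAnnotation",
    "COMPONENT_CODES",
    "isochrone_decompose",
    "identify_isthmus",
    "annotate_components",
    "NoIsthmusError",
]

N_BINS = 8
# package convention: mid-cycle isochrones (green/cyan of an 8-color map)
MID_BINS = (4, 5)

COMPONENT_CODES = {
    "none": 0,
    "outer_loop": 1,
    "entrance": 2,
    "isthmus": 3,
    "exit": 4,
    "common_pathway": 5,
}


class NoIsthmusError(RuntimeError):
    """No corridor-like candidate set intersects the reentry core region."""


@dataclass
class IsochroneMap:
    """Per-node isochrone bin (0..7; -1 = unactivated) plus bin windows."""

    bins: np.ndarray
    t0: float
    cycle_length: float

    @property
    def windows(self) -> list:
        w = self.cycle_length / N_BINS
        return [(self.t0 + k * w, self.t0 + (k + 1) * w) for k in range(N_BINS)]


@dataclass
class CircuitAnnotation:
    """Per-node circuit component codes (COMPONENT_CODES values)."""

    components: np.ndarray

    def nodes_of(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.components.ravel() == COMPONENT_CODES[name])


def isochrone_decompose(lat: np.ndarray, cycle_length: float,
                        t0: float | None = None) -> IsochroneMap:
    """Bin local activation times into eight uniform windows of one cycle.

    ``bin = floor(8 * ((LAT - t0) mod CL) / CL)`` with ``t0`` the earliest
    LAT in the cycle (lower-inclusive bin edges).  Unactivated nodes stay
    unset (-1).
    """
    if cycle_length <= 0:
        raise ValueError("cycle_length must be > 0")
    lat = np.asarray(lat, dtype=float)
    act = np.isfinite(lat)
    if t0 is None:
        if not act.any():
            raise ValueError("no activated nodes in the LAT map")
        t0 = float(np.nanmin(lat))
    bins = np.full(lat.shape, -1, dtype=np.int8)
    phase = np.mod(lat[act] - t0, cycle_length) / cycle_length
    b = np.floor(N_BINS * phase).astype(np.int8)
    b[b == N_BINS] = N_BINS - 1  # phase exactly 1.0 wraps to the last bin
    bins[act] = b
    return IsochroneMap(bins=bins, t0=float(t0), cycle_length=float(cycle_length))


def _corridor_candidates(domain: TissueDomain, corridor_halfwidth_mm: float
                         ) -> np.ndarray:
    """Conducting nodes walled by non-conducting tissue on two opposing
    sides within ``corridor_halfwidth_mm`` (distance-transform ray test)."""
    cond = domain.conducting
    if cond.ndim == 3:  # analyze in-plane on each slice
        return np.stack([
            _corridor_candidates_2d(cond[k], domain.h, corridor_halfwidth_mm)
            for k in range(cond.shape[0])
        ])
    return _corridor_candidates_2d(cond, domain.h, corridor_halfwidth_mm)


def _corridor_candidates_2d(cond: np.ndarray, h: float, halfwidth_mm: float
                            ) -> np.ndarray:
    """Two-opposing-sides ray test.  At least one of the two walls must be
    real non-conducting tissue (scar/lesion/background); the no-flux
    domain boundary may serve as the second wall (an edge corridor), but
    boundary-only pairs (sheet corners) do not qualify."""
    blocked = ~cond
    n_steps = max(1, int(np.ceil(halfwidth_mm / h)))
    ny, nx = cond.shape
    out = np.zeros_like(cond)
    directions = [(0, 1), (1, 0), (1, 1), (1, -1)]
    # padded masks: tissue obstruction only, and tissue-or-boundary
    pad_tis = np.zeros((ny + 2 * n_steps, nx + 2 * n_steps), dtype=bool)
    pad_tis[n_steps:-n_steps, n_steps:-n_steps] = blocked
    pad_any = np.ones((ny + 2 * n_steps, nx + 2 * n_steps), dtype=bool)
    pad_any[n_steps:-n_steps, n_steps:-n_steps] = blocked
    for dy, dx in directions:
        hp_t = np.zeros_like(cond)
        hm_t = np.zeros_like(cond)
        hp_a = np.zeros_like(cond)
        hm_a = np.zeros_like(cond)
        for s in range(1, n_steps + 1):
            if s * h * max(abs(dy), abs(dx)) > halfwidth_mm + 1e-9:
                break
            ys = slice(n_steps + dy * s, n_steps + dy * s + ny)
            xs = slice(n_steps + dx * s, n_steps + dx * s + nx)
            hp_t |= pad_tis[ys, xs]
            hp_a |= pad_any[ys, xs]
            ys = slice(n_steps - dy * s, n_steps - dy * s + ny)
            xs = slice(n_steps - dx * s, n_steps - dx * s + nx)
            hm_t |= pad_tis[ys, xs]
            hm_a |= pad_any[ys, xs]
        out |= (hp_t & hm_a) | (hp_a & hm_t)
    return out & cond


def identify_isthmus(iso: IsochroneMap, domain: TissueDomain,
                     episode: VTEpisode, mid_bins: tuple = MID_BINS,
                     corridor_halfwidth_mm: float = 4.0,
                     core_neighborhood_mm: float = 8.0):
    """Locate the critical isthmus of a sustained reentry.

    Candidates are conducting nodes in the mid-cycle isochrone bins that
    pass the two-opposing-sides corridor test; the isthmus is the largest
    connected candidate component intersecting the neighborhood of the
    reentry core trajectory.  Returns (flat node indices, center point mm);
    the center is the component medoid.
    """
    in_mid = np.isin(iso.bins, mid_bins)
    corridor = _corridor_candidates(domain, corridor_halfwidth_mm)
    cand = in_mid & corridor & domain.conducting
    if not cand.any():
        raise NoIsthmusError("no mid-cycle corridor candidates")
    struct = ndimage.generate_binary_structure(cand.ndim, 2)
    lab, n_comp = ndimage.label(cand, structure=struct)
    traj = np.atleast_2d(episode.core_trajectory)
    best_nodes, best_size = None, 0
    for k in range(1, n_comp + 1):
        nodes = np.flatnonzero((lab == k).ravel())
        xyz = domain.node_xyz(nodes)
        dmin = min(
            float(np.linalg.norm(xyz - c, axis=1).min()) for c in traj
        )
        if dmin <= core_neighborhood_mm and nodes.size > best_size:
            best_nodes, best_size = nodes, nodes.size
    if best_nodes is None:
        raise NoIsthmusError(
            "no corridor component within the reentry-core neighborhood"
        )
    xyz = domain.node_xyz(best_nodes)
    if best_nodes.size <= 4000:
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        center = xyz[int(np.argmin(d.sum(axis=1)))]
    else:  # medoid approximation for very large sets
        center = xyz[int(np.argmin(np.linalg.norm(xyz - xyz.mean(0), axis=1)))]
    return best_nodes, tuple(float(v) for v in center)


def annotate_components(iso: IsochroneMap, domain: TissueDomain,
                        isthmus_nodes: np.ndarray | None,
                        shared_isthmus_nodes: np.ndarray | None = None
                        ) -> CircuitAnnotation:
    """Label every activated conducting node with one circuit component.

    Entrance = nodes of bins 2-3 adjacent to the isthmus; exit = bins 6-7
    adjacent to it; common pathway = isthmus nodes shared across several
    episodes' corridors (``shared_isthmus_nodes``); all other activated
    conducting nodes form the outer loop.
    """
    comp = np.zeros(domain.shape, dtype=np.int8)
    activated = (iso.bins >= 0) & domain.conducting
    comp[activated] = COMPONENT_CODES["outer_loop"]
    if isthmus_nodes is not None and len(isthmus_nodes):
        isth = np.zeros(domain.shape, dtype=bool)
        isth.ravel()[isthmus_nodes] = True
        struct = ndimage.generate_binary_structure(comp.ndim, 2)
        halo = ndimage.binary_dilation(isth, structure=struct) & ~isth
        comp[isth] = COMPONENT_CODES["isthmus"]
        entrance = halo & np.isin(iso.bins, (2, 3)) & activated
        exit_ = halo & np.isin(iso.bins, (6, 7)) & activated
        comp[entrance] = COMPONENT_CODES["entrance"]
        comp[exit_] = COMPONENT_CODES["exit"]
        if shared_isthmus_nodes is not None and len(shared_isthmus_nodes):
            shared = np.zeros(domain.shape, dtype=bool)
            shared.ravel()[shared_isthmus_nodes] = True
            comp[isth & shared] = COMPONENT_CODES["common_pathway"]
    return CircuitAnnotation(components=comp)
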