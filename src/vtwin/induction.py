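"""Programmed-stimulation VT induction.

Implements the clinical rapid-pacing protocol on the digital substrate:
a drive train of S1 stimuli at 600 ms, then premature extrastimuli
(S2..S5) whose coupling interval is scanned downward in 10-ms steps.
Earlier extrastimuli are fixed at their shortest captured coupling when a
deeper stimulus is added.  A reentry that lasts two cycles at the same
critical site is a sustained episode; the protocol stops at the first
sustained episode.

The scan reuses state snapshots so the S1 drive is simulated once per
site and each coupling restarts from the stored state at its own onset
time.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass

import numpy as np

from .cells import paced_state
from .imaging import AHAMap
from .tissue import (
    DEFAULT_DT,
    DEFAULT_STIM_AMP,
    DEFAULT_STIM_DUR,
    TissueDomain,
    TissueSolver,
    deliver_stimulus,
)

log = logging.getLogger(__name__)

__all__ = [
    "PacingProtocol",
    "VTEpisode",
    "select_pacing_sites",
    "run_protocol",
    "detect_sustained",
    "dedupe_morphologies",
]


@dataclass(frozen=True)
class PacingProtocol:
    """Drive-train and extrastimulus schedule for one pacing site.

    Defaults follow the clinical protocol: six S1 at a 600-ms cycle
    length, S2 starting 250 ms after the last S1, couplings reduced in
    10-ms steps, and up to four extrastimuli (S2-S5).  ``n_s1 < 6`` with
    ``paced_init=True`` replaces leading drive beats by initializing the
    tissue at the single-cell limit cycle for the drive rate.
    """

    site: tuple = (0.0, 0.0, 0.0)
    n_s1: int = 6
    s1_cl: float = 600.0
    s2_initial: float = 250.0
    decrement: float = 10.0
    min_coupling: float = 180.0
    max_extrastimuli: int = 4
    stim_extent: float = 1.0        # mm^3 (3-D) or mm^2 (2-D)
    stim_amplitude: float = DEFAULT_STIM_AMP
    stim_duration: float = DEFAULT_STIM_DUR
    paced_init: bool = True
    observe_ms: float = 1200.0      # window after each extrastimulus
    capture_window_ms: float = 45.0
    expected_cl_ms: float = 350.0

    def __post_init__(self):
        if self.decrement <= 0:
            raise ValueError("decrement must be > 0")
        if self.s2_initial >= self.s1_cl:
            raise ValueError("S2 initial coupling must be shorter than the S1 cycle length")
        if not 1 <= self.max_extrastimuli <= 4:
            raise ValueError("max_extrastimuli must lie in 1..4 (S2-S5)")
        if self.n_s1 < 1:
            raise ValueError("n_s1 must be >= 1")

    @property
    def couplings(self) -> tuple:
        """The descending coupling scan, e.g. 250, 240, ..., min_coupling."""
        out, c = [], self.s2_initial
        while c >= self.min_coupling - 1e-9:
            out.append(round(c, 6))
            c -= self.decrement
        return tuple(out)


@dataclass
class VTEpisode:
    """A detected sustained reentry and its per-cycle bookkeeping."""

    site: tuple
    site_index: int
    couplings: tuple                 # coupling intervals of S2..Sk that induced it
    cycle_length_ms: float
    core_trajectory: np.ndarray      # (n_cycles, 3) mm
    chirality: int                   # +1 counter-clockwise, -1 clockwise
    duration_cycles: int
    t_final_stim: float
    cycle_window: tuple              # (t0, t1) of the analyzed cycle
    lat_cycle: np.ndarray            # grid LAT (ms) within the analyzed cycle
    core_segment: int = -1           # AHA segment of the mean core (set on demand)

    @property
    def core(self) -> np.ndarray:
        return self.core_trajectory.mean(axis=0)

    def morphology_signature(self, aha: AHAMap | None = None, h: float = 1.0):
        seg = self.core_segment
        if aha is not None:
            seg = _segment_of_point(aha, self.core, h)
        return (seg, round(self.cycle_length_ms, 1), self.chirality)


def _segment_of_point(aha: AHAMap, point_mm, h: float) -> int:
    seg2d = aha.segment[-1] if aha.segment.ndim == 3 else aha.segment
    iy = int(np.clip(round(point_mm[1] / h), 0, seg2d.shape[0] - 1))
    ix = int(np.clip(round(point_mm[0] / h), 0, seg2d.shape[1] - 1))
    return int(seg2d[iy, ix])


def select_pacing_sites(aha: AHAMap, domain: TissueDomain,
                        surface: np.ndarray | None = None) -> list:
    """One pacing point per AHA segment: the conducting surface node
    nearest the segment centroid (deterministic; ties by node order).

    For a 2-D sheet every conducting node is "surface"; for a slab the
    endocardial layer (z = 0) is used.  Segments without a conducting
    surface node are skipped with a warning.
    """
    cond = domain.conducting
    if surface is None:
        surface = np.ones(domain.shape, dtype=bool)
        if domain.ndim == 3:
            surface[1:] = False
    seg = aha.segment
    if seg.shape != domain.shape:
        seg = np.broadcast_to(seg[-1] if seg.ndim == 3 else seg, domain.shape)
    sites = []
    flat_ok = (cond & surface).ravel()
    for k in range(9):
        seg_mask = (seg == k).ravel()
        nodes = np.flatnonzero(seg_mask & flat_ok)
        if nodes.size == 0:
            log.warning("AHA segment %d has no conducting surface node; site skipped", k)
            continue
        all_nodes = np.flatnonzero(seg_mask)
        centroid = domain.node_xyz(all_nodes).mean(axis=0)
        xyz = domain.node_xyz(nodes)
        d2 = ((xyz - centroid) ** 2).sum(axis=1)
        best = nodes[int(np.argmin(d2))]
        sites.append(tuple(domain.node_xyz(np.array([best]))[0]))
    return sites


def _initial_state(domain: TissueDomain, solver: TissueSolver,
                   protocol: PacingProtocol) -> np.ndarray | None:
    if not protocol.paced_init:
        return None
    labels = domain.tissue.ravel()[solver.active]
    state = np.empty((solver.active.size, solver.state.shape[1]))
    for lab, params in domain.phenotypes.items():
        vec = paced_state(params, protocol.s1_cl, 8)
        state[labels == lab] = vec
    return state


def run_protocol(domain: TissueDomain, protocol: PacingProtocol,
                 dt: float = DEFAULT_DT, site_index: int = 0,
                 stop_at_first: bool = True) -> list:
    """Execute the full S1-S5 protocol from one site.

    Returns a list with the first sustained :class:`VTEpisode` found, or
    an empty list if the protocol exhausts without induction.  Couplings
    that fail to capture are skipped; a stage in which no coupling
    captured ends the protocol (deeper stimuli cannot be delivered).
    """
    solver = TissueSolver(domain, dt=dt)
    init = _initial_state(domain, solver, protocol)
    if init is not None:
        solver.state = init

    def stim_at(t):
        return deliver_stimulus(domain, protocol.site, protocol.stim_extent,
                                t_start=t, amplitude=protocol.stim_amplitude,
                                duration=protocol.stim_duration)

    # S1 drive up to the onset of the last S1
    t_last_s1 = (protocol.n_s1 - 1) * protocol.s1_cl
    if t_last_s1 > 0:
        drive = [stim_at(i * protocol.s1_cl) for i in range(protocol.n_s1 - 1)]
        solver.run(drive, t_last_s1, quiesce_after=t_last_s1 + 1.0)

    couplings = protocol.couplings
    fixed: list = []
    ref_time = t_last_s1
    t_wall = _time.time()
    for stage in range(protocol.max_extrastimuli):
        log.info("site %s stage S%d (%.0fs elapsed)", site_index, stage + 2,
                 _time.time() - t_wall)
        # one forward pass delivering the reference stimulus, snapshotting
        # the state at every candidate coupling of this stage
        ref_stim = stim_at(ref_time)
        snaps = {}
        for c in sorted(couplings):
            solver.run([ref_stim], ref_time + c, quiesce_after=ref_time + c + 1.0)
            snaps[c] = solver.checkpoint()
        shortest_captured = None
        for c in couplings:  # descending scan
            solver.restore(snaps[c])
            t_s = ref_time + c
            stim = stim_at(t_s)
            res1 = solver.run([stim], t_s + protocol.capture_window_ms,
                              quiesce_after=t_s + protocol.stim_duration + 1.0)
            outside = ~np.isin(res1.events_node, stim.nodes)
            captured = bool(np.any(outside & (res1.events_time > t_s)))
            if not captured:
                continue
            shortest_captured = c
            ev_nodes = [res1.events_node]
            ev_times = [res1.events_time]
            if res1.status != "quiescent":
                res2 = solver.run([], t_s + protocol.observe_ms,
                                  quiesce_after=t_s + protocol.capture_window_ms)
                ev_nodes.append(res2.events_node)
                ev_times.append(res2.events_time)
            episode = detect_sustained(
                np.concatenate(ev_nodes), np.concatenate(ev_times),
                domain, t_final_stim=t_s,
                expected_cl=protocol.expected_cl_ms,
            )
            if episode is not None:
                episode.site = tuple(protocol.site)
                episode.site_index = site_index
                episode.couplings = tuple(fixed + [c])
                if stop_at_first:
                    return [episode]
        if shortest_captured is None:
            log.info("stage S%d: no coupling captured; protocol ends", stage + 2)
            break
        fixed.append(shortest_captured)
        solver.restore(snaps[shortest_captured])
        ref_time = ref_time + shortest_captured
    return []


def detect_sustained(events_node: np.ndarray, events_time: np.ndarray,
                     domain: TissueDomain, t_final_stim: float,
                     expected_cl: float = 350.0, core_radius_mm: float = 5.0,
                     min_cycles: int = 2, settle_ms: float = 5.0,
                     min_active_fraction: float = 0.05) -> VTEpisode | None:
    """Scan post-stimulus activation events for sustained reentry.

    Re-excitation (>= 2 threshold crossings of the same node after the
    final stimulus) defines reentrant activity.  The cycle length is the
    median inter-crossing interval; activity is divided into consecutive
    cycle windows and the per-cycle core is the centroid of the
    earliest-reactivating decile of each window.  The episode is
    sustained if at least ``min_cycles`` consecutive cycles keep the core
    within ``core_radius_mm`` of the previous one ("same critical site").
    """
    sel = events_time > t_final_stim + settle_ms
    nodes, times = events_node[sel], events_time[sel]
    if nodes.size == 0:
        return None
    order = np.argsort(nodes, kind="stable")
    nodes_s, times_s = nodes[order], times[order]
    # consecutive crossings of the same node
    same = nodes_s[1:] == nodes_s[:-1]
    if not same.any():
        return None
    # note: within one node, events are chronological (kernel emits in time order)
    intervals = times_s[1:][same] - times_s[:-1][same]
    intervals = intervals[intervals > 20.0]
    if intervals.size == 0:
        return None
    # sustained reentry re-excites a substantial tissue fraction, unlike
    # localized electrotonic flutter at a block site
    re_nodes = np.unique(nodes_s[1:][same])
    if re_nodes.size < min_active_fraction * domain.conducting.sum():
        return None
    cl = float(np.median(intervals))
    if cl < 100.0:  # implausibly short for reentry through a corridor
        return None
    second_cross = times_s[1:][same]
    t_r = float(second_cross.min())
    n_cond = int(domain.conducting.sum())
    t_max = float(times.max())
    cores, k = [], 0
    while True:
        w0 = t_r + k * cl
        w1 = w0 + cl
        if w1 > t_max + 1.0:  # only complete cycles count
            break
        in_w = (times >= w0) & (times < w1)
        w_nodes, w_times = nodes[in_w], times[in_w]
        uniq = np.unique(w_nodes)
        if uniq.size < min_active_fraction * n_cond:
            break
        prev = cores[-1] if cores else None
        cores.append(_phase_core(w_nodes, w_times, domain, w0, cl, prev=prev))
        k += 1
        if k > 64:
            break
    if len(cores) < min_cycles:
        return None
    cores = np.asarray(cores)
    steps = np.linalg.norm(np.diff(cores, axis=0), axis=1)
    run_len = 1
    best_start, best_len = 0, 1
    for i, s_ in enumerate(steps):
        if s_ <= core_radius_mm:
            run_len += 1
        else:
            run_len = 1
        if run_len > best_len:
            best_len, best_start = run_len, i + 2 - run_len
    if best_len < min_cycles:
        return None
    cores = cores[best_start: best_start + best_len]
    # Analyzed cycle: one full window of the sustained run, phase-aligned
    # so the diastolic interval (fewest activations; the slow corridor
    # crawl) is centered on isochrone bins 4-5 — the mid-cycle "green and
    # cyan" convention that puts the entrance in bins 2-3 and the exit in
    # bins 6-7.
    k_last = best_start + best_len - 1
    w0 = t_r + k_last * cl
    phases = np.mod(times - t_r, cl)
    n_ph = 32
    counts = np.histogram(phases, bins=n_ph, range=(0.0, cl))[0]
    width = max(1, n_ph // 8)
    kernel_sums = np.array([
        counts.take(range(i, i + width), mode="wrap").sum() for i in range(n_ph)
    ])
    dia_center = (int(np.argmin(kernel_sums)) + width / 2.0) / n_ph * cl
    shift = float(np.mod(dia_center - 9.0 / 16.0 * cl, cl))
    w0 = w0 + shift
    if w0 + cl > t_max + 1.0:
        w0 -= cl
    lat = np.full(domain.shape, np.nan)
    in_w = (times >= w0) & (times < w0 + cl)
    flat = lat.reshape(-1)
    o = np.argsort(times[in_w])[::-1]
    flat[nodes[in_w][o]] = times[in_w][o]
    chir = _chirality(nodes[in_w], times[in_w], domain, cores[-1], cl)
    return VTEpisode(
        site=(np.nan, np.nan, np.nan), site_index=-1, couplings=(),
        cycle_length_ms=cl, core_trajectory=cores, chirality=chir,
        duration_cycles=best_len, t_final_stim=t_final_stim,
        cycle_window=(w0, w0 + cl), lat_cycle=lat,
    )


def _phase_core(nodes, times, domain, w0, cl, probe_radius_mm=4.0,
                lattice_mm=2.0, prev=None, track_radius_mm=4.0) -> np.ndarray:
    """Phase-singularity proxy: the lattice point where local activation
    phases cancel (minimum normalized resultant of e^{i phase} over the
    nodes within ``probe_radius_mm``).  At a rotor core every phase of
    the cycle is represented nearby; on a plane wave the local phases
    align.  A figure-of-eight has two such points; with ``prev`` given,
    the minimum near the previously tracked core is preferred so one
    singularity is followed across cycles.
    """
    from scipy.spatial import cKDTree

    xyz = domain.node_xyz(nodes)
    phase = np.exp(2j * np.pi * (times - w0) / cl)
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    axes = [np.arange(lo[d], hi[d] + 1e-9, lattice_mm) if hi[d] > lo[d]
            else np.array([lo[d]]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cand = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    tree = cKDTree(xyz)
    resultant = np.full(len(cand), np.inf)
    for j, p in enumerate(cand):
        idx = tree.query_ball_point(p, probe_radius_mm)
        if len(idx) < 12:
            continue
        resultant[j] = np.abs(phase[idx].mean())
    if not np.isfinite(resultant).any():
        # sparse activity: fall back to the earliest decile centroid
        t_dec = np.quantile(times, 0.10)
        early = np.unique(nodes[times <= t_dec])
        return domain.node_xyz(early).mean(axis=0)
    if prev is not None:
        near = np.linalg.norm(cand - np.asarray(prev), axis=1) <= track_radius_mm
        if near.any() and resultant[near].min() <= max(0.5, 1.5 * resultant.min()):
            sub = np.flatnonzero(near)
            return cand[sub[int(np.argmin(resultant[near]))]].astype(float)
    return cand[int(np.argmin(resultant))].astype(float)


def _chirality(nodes, times, domain, core, cl) -> int:
    """Rotation sense of the activation sequence around the core.

    Compares the circular correlation of activation phase with +/- the
    polar angle; +1 = counter-clockwise in the (x, y) plane.
    """
    if nodes.size == 0:
        return 1
    xyz = domain.node_xyz(nodes)
    rel = xyz - np.asarray(core)
    r = np.hypot(rel[:, 0], rel[:, 1])
    ring = (r > 1.5) & (r < 8.0)
    if ring.sum() < 8:
        ring = r > 0.5
    theta = np.arctan2(rel[ring, 1], rel[ring, 0])
    phase = 2.0 * np.pi * (times[ring] % cl) / cl
    z_ccw = np.abs(np.exp(1j * (phase - theta)).sum())
    z_cw = np.abs(np.exp(1j * (phase + theta)).sum())
    return 1 if z_ccw >= z_cw else -1


def dedupe_morphologies(episodes: list, aha: AHAMap | None = None,
                        h: float = 1.0, cl_tol: float = 10.0) -> list:
    """Unique VT morphologies.

    Two episodes are the same morphology iff their mean cores lie in the
    same AHA segment, their cycle lengths agree within ``cl_tol`` ms, and
    they share chirality.  The first episode (by input order) represents
    each class.
    """
    unique: list = []
    for ep in episodes:
        seg, cl, chir = ep.morphology_signature(aha, h)
        dup = any(
            seg == u.morphology_signature(aha, h)[0]
            and abs(cl - u.cycle_length_ms) <= cl_tol
            and chir == u.chirality
            for u in unique
        )
        if not dup:
            unique.append(ep)
    return unique
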