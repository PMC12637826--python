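"""Monodomain reaction–diffusion simulation on structured 2-D/3-D grids.

The membrane model comes from :mod:`vtwin.cells`; tissue-level propagation
uses an anisotropic 9-point (in-plane) finite-difference stencil with
no-flux boundaries.  Conductivities are expressed directly as effective
diffusivities (mm^2/ms).  Dense scar and ablation lesions are electrical
insulators: they carry no conductivity, are excluded from the update, and
never activate.

Physical coordinates are voxel-center based: node (iz, iy, ix) sits at
(x, y, z) = (ix*h, iy*h, iz*h) mm.  Points are (x, y, z) triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from . import _tt2
from .cells import IonicModelParams, NumericalInstabilityError, tables_for
from .labels import FIBROSIS, NORMAL

__all__ = [
    "TissueDomain",
    "FiberRule",
    "StimulusEvent",
    "SimResult",
    "ActivationMap",
    "TissueSolver",
    "PropagationFailureError",
    "CalibrationResult",
    "assign_fibers",
    "deliver_stimulus",
    "simulate",
    "measure_cv",
    "calibrate_conductivity",
    "make_sheet",
    "make_strand",
]

DEFAULT_DT = 0.05          # ms (tissue); single-cell default is finer
DEFAULT_STIM_AMP = 52.0    # pA/pF, ~2x diastolic threshold
DEFAULT_STIM_DUR = 2.0     # ms
ACTIVATION_THRESHOLD = -40.0  # mV, upward crossing


class PropagationFailureError(RuntimeError):
    """Raised when an expected wavefront fails to reach a probe."""


@dataclass
class TissueDomain:
    """Structured-grid substrate: tissue class, fibers and conductivity.

    Arrays share one shape, either (ny, nx) for a sheet or (nz, ny, nx)
    for a slab.  ``sigma_l``/``sigma_t`` are longitudinal/transverse
    effective diffusivities (mm^2/ms); they are ignored on scar/lesion
    nodes, which are insulating.
    """

    h: float                      # isotropic grid spacing, mm
    tissue: np.ndarray            # uint8 label codes
    fiber_theta_deg: np.ndarray   # in-plane fiber angle per node
    sigma_l: np.ndarray
    sigma_t: np.ndarray
    lesion: np.ndarray = None     # bool; created on demand
    phenotypes: dict = field(default_factory=dict)  # label -> IonicModelParams

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("grid spacing h must be > 0")
        if self.lesion is None:
            self.lesion = np.zeros(self.tissue.shape, dtype=bool)
        for name in ("fiber_theta_deg", "sigma_l", "sigma_t", "lesion"):
            if getattr(self, name).shape != self.tissue.shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != tissue shape")
        cond = self.conducting
        sl, st = self.sigma_l[cond], self.sigma_t[cond]
        if cond.any() and (np.any(st <= 0) or np.any(sl < st)):
            raise ValueError("conducting nodes require sigma_l >= sigma_t > 0")
        if not self.phenotypes:
            self.phenotypes = {
                NORMAL: IonicModelParams.for_phenotype("GE"),
                FIBROSIS: IonicModelParams.for_phenotype("FIB"),
            }

    @property
    def shape(self) -> tuple:
        return self.tissue.shape

    @property
    def ndim(self) -> int:
        return self.tissue.ndim

    @property
    def conducting(self) -> np.ndarray:
        return ((self.tissue == NORMAL) | (self.tissue == FIBROSIS)) & ~self.lesion

    def node_xyz(self, flat_idx: np.ndarray) -> np.ndarray:
        """(x, y, z) mm coordinates of flattened grid indices."""
        idx = np.unravel_index(np.asarray(flat_idx), self.shape)
        if self.ndim == 2:
            iy, ix = idx
            iz = np.zeros_like(ix)
        else:
            iz, iy, ix = idx
        return np.stack([ix, iy, iz], axis=-1) * self.h

    def nearest_node(self, point) -> tuple:
        """Grid index tuple of the node nearest a physical point."""
        x, y, z = (list(point) + [0.0])[:3]
        ix = int(round(x / self.h))
        iy = int(round(y / self.h))
        iz = int(round(z / self.h))
        if self.ndim == 2:
            if not (0 <= iy < self.shape[0] and 0 <= ix < self.shape[1]):
                raise ValueError(f"point {point} outside domain")
            return (iy, ix)
        if not (0 <= iz < self.shape[0] and 0 <= iy < self.shape[1] and 0 <= ix < self.shape[2]):
            raise ValueError(f"point {point} outside domain")
        return (iz, iy, ix)

    def copy(self) -> "TissueDomain":
        return TissueDomain(
            h=self.h,
            tissue=self.tissue.copy(),
            fiber_theta_deg=self.fiber_theta_deg.copy(),
            sigma_l=self.sigma_l.copy(),
            sigma_t=self.sigma_t.copy(),
            lesion=self.lesion.copy(),
            phenotypes=dict(self.phenotypes),
        )


@dataclass(frozen=True)
class FiberRule:
    """Fiber assignment rule: uniform sheet angle or linear transmural
    rotation from ``angle_endo_deg`` (layer 0) to ``angle_epi_deg``."""

    kind: str = "uniform"          # "uniform" | "slab"
    angle_deg: float = 0.0
    angle_endo_deg: float = 60.0
    angle_epi_deg: float = -60.0

    def __post_init__(self):
        for a in (self.angle_deg, self.angle_endo_deg, self.angle_epi_deg):
            if not -90.0 <= a <= 90.0:
                raise ValueError("fiber angles must lie within [-90, 90] degrees")


def assign_fibers(domain: TissueDomain, rule: FiberRule) -> TissueDomain:
    """Return a copy of ``domain`` with fiber angles set by ``rule``.

    Sheets get a uniform angle; slabs a linear endo-to-epi rotation
    across layers (layer 0 = endocardium).
    """
    out = domain.copy()
    if rule.kind == "uniform" or domain.ndim == 2:
        angle = rule.angle_deg if rule.kind == "uniform" else rule.angle_endo_deg
        out.fiber_theta_deg[...] = angle
        return out
    if rule.kind != "slab":
        raise ValueError(f"unknown fiber rule kind {rule.kind!r}")
    nz = domain.shape[0]
    depth = np.linspace(0.0, 1.0, nz) if nz > 1 else np.array([0.5])
    angles = rule.angle_endo_deg + (rule.angle_epi_deg - rule.angle_endo_deg) * depth
    out.fiber_theta_deg[...] = angles[:, None, None]
    return out


@dataclass(frozen=True)
class StimulusEvent:
    """A current injection into a fixed node set."""

    t_start: float
    duration: float
    amplitude: float          # pA/pF, positive depolarizes
    nodes: np.ndarray         # flattened grid indices

    def shifted(self, dt_ms: float) -> "StimulusEvent":
        return replace(self, t_start=self.t_start + dt_ms)


def deliver_stimulus(domain: TissueDomain, site, extent: float = 1.0,
                     t_start: float = 0.0, amplitude: float = DEFAULT_STIM_AMP,
                     duration: float = DEFAULT_STIM_DUR) -> StimulusEvent:
    """Stimulus over a cube (3-D, ``extent`` mm^3) or square patch
    (2-D, ``extent`` mm^2) centered at ``site``; clipped to the domain.

    Falls back to the nearest conducting node when the extent is smaller
    than one voxel.  Raises if the site itself is inside scar or lesion.
    """
    idx = domain.nearest_node(site)
    if not domain.conducting[idx]:
        raise ValueError(f"stimulus site {site} is not conducting tissue")
    side = extent ** (1.0 / domain.ndim)
    half = side / 2.0
    xyz = np.asarray((list(site) + [0.0])[:3], dtype=float)
    coords = domain.node_xyz(np.arange(domain.tissue.size))
    within = np.all(np.abs(coords[:, :domain.ndim] - xyz[:domain.ndim]) <= half + 1e-9, axis=1)
    within &= domain.conducting.ravel()
    nodes = np.flatnonzero(within)
    if nodes.size == 0:
        nodes = np.array([np.ravel_multi_index(idx, domain.shape)])
    return StimulusEvent(t_start=float(t_start), duration=float(duration),
                         amplitude=float(amplitude), nodes=nodes)


@dataclass
class ActivationMap:
    """Local activation time (ms) per node; NaN = never activated."""

    lat: np.ndarray
    threshold_mv: float = ACTIVATION_THRESHOLD

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.lat)


@dataclass
class SimResult:
    """Outcome of a tissue simulation.

    ``events`` is the chronological log of activation-threshold crossings
    as (flat node index, time ms).  ``vm_samples`` holds Vm on the full
    grid at ``sample_times`` (NaN outside conducting tissue).
    """

    domain: TissueDomain
    t_end: float
    status: str                       # "completed" | "quiescent" | ...
    events_node: np.ndarray
    events_time: np.ndarray
    sample_times: np.ndarray
    vm_samples: np.ndarray | None
    final_state: np.ndarray           # solver state (n_active, N_STATE)
    stimuli: tuple = ()

    def activation_map(self, t_from: float = -np.inf, t_to: float = np.inf) -> ActivationMap:
        """First-crossing LAT map restricted to a time window."""
        lat = np.full(self.domain.shape, np.nan)
        sel = (self.events_time >= t_from) & (self.events_time < t_to)
        nodes, times = self.events_node[sel], self.events_time[sel]
        order = np.argsort(times)[::-1]  # earliest written last
        flat = lat.reshape(-1)
        flat[nodes[order]] = times[order]
        return ActivationMap(lat=lat)

    def crossings_after(self, t0: float):
        sel = self.events_time >= t0
        return self.events_node[sel], self.events_time[sel]


def _diffusion_tensor(domain: TissueDomain):
    th = np.deg2rad(domain.fiber_theta_deg)
    c, s = np.cos(th), np.sin(th)
    sl, st = domain.sigma_l, domain.sigma_t
    dxx = sl * c * c + st * s * s
    dyy = sl * s * s + st * c * c
    dxy = (sl - st) * c * s
    return dxx, dyy, dxy


def build_operator(domain: TissueDomain) -> tuple[np.ndarray, sp.csr_matrix]:
    """Active-node index and the CSR diffusion operator over active nodes.

    The stencil is flux-conservative: weights between conducting neighbor
    pairs are face-averaged tensor entries, the diagonal balances the row
    to zero, and contributions across non-conducting faces are dropped
    (homogeneous Neumann / mirror condition).
    """
    cond = domain.conducting
    n_total = cond.size
    active = np.flatnonzero(cond.ravel())
    glob2act = np.full(n_total, -1, dtype=np.int64)
    glob2act[active] = np.arange(active.size)
    dxx, dyy, dxy = _diffusion_tensor(domain)
    h2 = domain.h ** 2
    shape = domain.shape
    if domain.ndim == 2:
        offsets = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1), (1, -1), (-1, 1)]
    else:
        offsets = [
            (0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0),
            (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
        ]
    rows, cols, vals = [], [], []
    diag = np.zeros(active.size)
    grid_idx = np.arange(n_total).reshape(shape)
    for off in offsets:
        src = [slice(None)] * domain.ndim
        dst = [slice(None)] * domain.ndim
        for ax, d in enumerate(off):
            if d == 1:
                src[ax] = slice(0, shape[ax] - 1)
                dst[ax] = slice(1, shape[ax])
            elif d == -1:
                src[ax] = slice(1, shape[ax])
                dst[ax] = slice(0, shape[ax] - 1)
        src, dst = tuple(src), tuple(dst)
        i_idx = grid_idx[src].ravel()
        j_idx = grid_idx[dst].ravel()
        ok = cond.ravel()[i_idx] & cond.ravel()[j_idx]
        i_idx, j_idx = i_idx[ok], j_idx[ok]
        in_plane = off[-2:] if domain.ndim == 3 else off
        if domain.ndim == 3 and off[0] != 0:
            # transmural face: sheet-normal diffusivity = sigma_t
            w = 0.5 * (domain.sigma_t.ravel()[i_idx] + domain.sigma_t.ravel()[j_idx]) / h2
        elif abs(in_plane[0]) + abs(in_plane[1]) == 1:
            dax = dxx if in_plane[1] != 0 else dyy
            w = 0.5 * (dax.ravel()[i_idx] + dax.ravel()[j_idx]) / h2
        else:
            sign = 1.0 if in_plane[0] * in_plane[1] > 0 else -1.0
            w = sign * 0.25 * (dxy.ravel()[i_idx] + dxy.ravel()[j_idx]) / h2
        ai, aj = glob2act[i_idx], glob2act[j_idx]
        rows.append(ai)
        cols.append(aj)
        vals.append(w)
        np.add.at(diag, ai, -w)
    rows.append(np.arange(active.size))
    cols.append(np.arange(active.size))
    vals.append(diag)
    w_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(active.size, active.size),
    )
    return active, w_mat


class TissueSolver:
    """Stateful monodomain integrator bound to one domain configuration."""

    def __init__(self, domain: TissueDomain, dt: float = DEFAULT_DT,
                 init: str | np.ndarray = "rest"):
        if not (0 < dt <= 0.05):
            raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
        self.domain = domain
        self.dt = float(dt)
        self.active, self.w = build_operator(domain)
        if self.active.size == 0:
            raise ValueError("domain has no conducting nodes")
        # CFL-style stability check for the explicit diffusion update
        lam = float(np.abs(self.w).sum(axis=1).max())  # >= spectral radius (Gershgorin)
        if dt * lam > 2.0:
            raise ValueError(
                f"unstable discretization: dt*|W|_inf = {dt * lam:.2f} > 2 "
                f"(reduce dt or conductivity, or refine h)"
            )
        self.wp = self.w.indptr.astype(np.int64)
        self.wi = self.w.indices.astype(np.int64)
        self.wx = self.w.data
        labels = domain.tissue.ravel()[self.active]
        phen_labels = sorted(domain.phenotypes)
        self.phen = np.zeros(self.active.size, dtype=np.int8)
        scale_rows = []
        for k, lab in enumerate(phen_labels):
            self.phen[labels == lab] = k
            scale_rows.append(domain.phenotypes[lab].scale_row())
        self.scales = np.asarray(scale_rows)
        if isinstance(init, np.ndarray):
            self.state = init.copy()
        else:
            self.state = np.tile(_tt2.resting_state(), (self.active.size, 1))
        self.t = 0.0
        self._tab, self._k1tab = tables_for(self.dt)

    def checkpoint(self) -> tuple[float, np.ndarray]:
        return self.t, self.state.copy()

    def restore(self, chk: tuple[float, np.ndarray]) -> None:
        self.t = chk[0]
        self.state = chk[1].copy()

    def _stim_arrays(self, stimuli: Sequence[StimulusEvent]):
        glob2act = np.full(self.domain.tissue.size, -1, dtype=np.int64)
        glob2act[self.active] = np.arange(self.active.size)
        starts, durs, amps, ptr, idx = [], [], [], [0], []
        for ev in stimuli:
            nodes = glob2act[ev.nodes]
            nodes = nodes[nodes >= 0]
            starts.append(ev.t_start)
            durs.append(ev.duration)
            amps.append(ev.amplitude)
            idx.extend(nodes.tolist())
            ptr.append(len(idx))
        return (
            np.asarray(starts, dtype=np.float64),
            np.asarray(durs, dtype=np.float64),
            np.asarray(amps, dtype=np.float64),
            np.asarray(ptr, dtype=np.int64),
            np.asarray(idx, dtype=np.int64),
        )

    def run(self, stimuli: Sequence[StimulusEvent], t_end: float,
            sample_every_ms: float = 0.0, quiesce_after: float | None = None,
            event_capacity_per_node: int = 48) -> SimResult:
        """Integrate until ``t_end`` (absolute time).

        ``quiesce_after``: absolute time after which a fully repolarized
        tissue (max Vm < -70 mV, no pending stimulus) ends the run early;
        ``None`` derives it from the last stimulus.
        """
        for ev in stimuli:
            if np.any(ev.nodes >= self.domain.tissue.size) or np.any(ev.nodes < 0):
                raise ValueError("stimulus addresses nodes outside the domain")
        n = self.active.size
        n_steps = int(round((t_end - self.t) / self.dt))
        if n_steps <= 0:
            raise ValueError("t_end must exceed current solver time")
        s_start, s_dur, s_amp, s_ptr, s_idx = self._stim_arrays(stimuli)
        e_rev = np.zeros((n, 4))
        last_cross = np.full(n, -1.0)
        armed = np.ones(n, dtype=np.int8)
        cap = n * event_capacity_per_node
        ev_node = np.zeros(cap, dtype=np.int64)
        ev_time = np.zeros(cap)
        ev_count = np.zeros(1, dtype=np.int64)
        if sample_every_ms > 0:
            sample_every = max(1, int(round(sample_every_ms / self.dt)))
            n_samp = n_steps // sample_every
            sample_buf = np.empty((n_samp, n))
        else:
            sample_every = 0
            sample_buf = np.empty((0, n))
        if quiesce_after is None:
            ends = [ev.t_start + ev.duration for ev in stimuli]
            quiesce_after = (max(ends) + 5.0) if ends else self.t
        diff_scratch = np.zeros(n)
        t_reached, status = _tt2.run_chunk(
            self.state, self.phen, self.scales, self._tab, self._k1tab,
            self.wp, self.wi, self.wx, self.dt, self.t, n_steps,
            s_start, s_dur, s_amp, s_ptr, s_idx,
            e_rev, 10, last_cross, armed, ev_node, ev_time, ev_count,
            sample_buf, sample_every, diff_scratch, float(quiesce_after),
        )
        if status == 2:
            raise NumericalInstabilityError(
                f"membrane potential left [-200, 200] mV at t = {t_reached:.2f} ms"
            )
        t0 = self.t
        self.t = t_reached
        nev = int(ev_count[0])
        vm = None
        times = np.array([])
        if sample_every:
            n_have = min(sample_buf.shape[0], int((t_reached - t0) / (self.dt * sample_every)))
            times = t0 + self.dt * sample_every * (1 + np.arange(n_have))
            vm = np.full((n_have, self.domain.tissue.size), np.nan)
            vm[:, self.active] = sample_buf[:n_have]
            vm = vm.reshape((n_have,) + self.domain.shape)
        return SimResult(
            domain=self.domain, t_end=t_reached,
            status={0: "completed", 1: "quiescent"}[status],
            events_node=self.active[ev_node[:nev]], events_time=ev_time[:nev].copy(),
            sample_times=times, vm_samples=vm, final_state=self.state.copy(),
            stimuli=tuple(stimuli),
        )


def simulate(domain: TissueDomain, stimuli: Sequence[StimulusEvent], t_end: float,
             dt: float = DEFAULT_DT, sample_every_ms: float = 1.0) -> SimResult:
    """Convenience one-shot simulation from rest; see :class:`TissueSolver`."""
    solver = TissueSolver(domain, dt=dt)
    return solver.run(stimuli, t_end, sample_every_ms=sample_every_ms)


def make_sheet(ny: int, nx: int, h: float = 0.25, sigma_l: float = 0.15,
               sigma_t: float = 0.05, theta_deg: float = 0.0,
               phenotypes: dict | None = None) -> TissueDomain:
    """Homogeneous conducting sheet (all NORMAL tissue)."""
    tissue = np.full((ny, nx), NORMAL, dtype=np.uint8)
    dom = TissueDomain(
        h=h, tissue=tissue,
        fiber_theta_deg=np.full((ny, nx), float(theta_deg)),
        sigma_l=np.full((ny, nx), float(sigma_l)),
        sigma_t=np.full((ny, nx), float(sigma_t)),
    )
    if phenotypes:
        dom.phenotypes = phenotypes
    return dom


def make_strand(length_mm: float = 40.0, width_mm: float = 1.0, h: float = 0.25,
                sigma: float = 0.15, along_fibers: bool = True,
                model: IonicModelParams | None = None) -> TissueDomain:
    """Thin strand along x for conduction-velocity measurements.

    ``along_fibers`` selects whether propagation along x is longitudinal
    (fibers at 0 deg, sigma_l = sigma) or transverse (fibers at 90 deg,
    sigma_t = sigma).
    """
    nx = int(round(length_mm / h)) + 1
    ny = max(3, int(round(width_mm / h)) + 1)
    if along_fibers:
        dom = make_sheet(ny, nx, h, sigma_l=sigma, sigma_t=max(sigma / 9, 1e-5), theta_deg=0.0)
        dom.sigma_t = np.minimum(dom.sigma_l, dom.sigma_t)
    else:
        dom = make_sheet(ny, nx, h, sigma_l=max(sigma, 1e-5), sigma_t=sigma, theta_deg=90.0)
    if model is not None:
        dom.phenotypes = {NORMAL: model}
    return dom


def measure_cv(domain: TissueDomain, direction=(1.0, 0.0, 0.0),
               model: IonicModelParams | None = None, dt: float = DEFAULT_DT,
               t_max: float = 800.0, probe_lo: float = 0.25,
               probe_hi: float = 0.75) -> float:
    """Plane-wave conduction velocity (mm/ms) along ``direction``.

    A stimulus covers the upstream end; CV = distance / LAT difference
    between probes at the ``probe_lo`` and ``probe_hi`` fractions of the
    conducting extent along the direction (central region, away from
    boundary effects).
    """
    if model is not None:
        domain = domain.copy()
        domain.phenotypes = {k: model for k in domain.phenotypes}
    d = np.asarray(direction, dtype=float)[:3]
    d = d / np.linalg.norm(d)
    cond_flat = np.flatnonzero(domain.conducting.ravel())
    xyz = domain.node_xyz(cond_flat)
    proj = xyz @ d
    lo, hi = proj.min(), proj.max()
    # stimulate a 1-mm slab at the upstream end
    stim_nodes = cond_flat[proj <= lo + 1.0]
    stim = StimulusEvent(t_start=1.0, duration=DEFAULT_STIM_DUR,
                         amplitude=DEFAULT_STIM_AMP, nodes=stim_nodes)
    solver = TissueSolver(domain, dt=dt)
    res = solver.run([stim], t_max, quiesce_after=5.0)
    lat = res.activation_map().lat.ravel()
    cvs = []
    p_lo = lo + probe_lo * (hi - lo)
    p_hi = lo + probe_hi * (hi - lo)
    for p in (p_lo, p_hi):
        near = cond_flat[np.abs(proj - p) <= domain.h * 0.6]
        if near.size == 0 or not np.any(np.isfinite(lat[near])):
            raise PropagationFailureError(
                f"wavefront did not reach the probe at projection {p:.1f} mm"
            )
        cvs.append(np.nanmedian(lat[near]))
    dt_lat = cvs[1] - cvs[0]
    if dt_lat <= 0:
        raise PropagationFailureError("non-positive LAT difference between probes")
    return float((p_hi - p_lo) / dt_lat)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the logarithmic CV-conductivity calibration."""

    sigma: float
    target_cv: float
    slope: float          # a in CV = a*ln(sigma) + b
    intercept: float
    r_squared: float
    probe_sigmas: tuple
    probe_cvs: tuple
    residuals: tuple


def calibrate_conductivity(model: IonicModelParams, target_cv: float,
                           direction: str = "L",
                           probe_sigmas: Iterable[float] | None = None,
                           h: float = 0.25, dt: float = DEFAULT_DT) -> CalibrationResult:
    """Conductivity that yields ``target_cv`` via logarithmic fitting.

    CV is measured on a homogeneous strand over a coarse probe ladder to
    bracket the target, then CV = a*ln(sigma) + b is fitted over >= 4
    probes concentrated around the bracket (the relationship is close to
    CV ~ sqrt(sigma) globally, so the logarithmic law is applied locally)
    and sigma* = exp((target - b)/a) is returned.  Raises if the target
    lies outside the CV range the probes can reach.
    """
    if direction not in ("L", "T"):
        raise ValueError("direction must be 'L' (longitudinal) or 'T' (transverse)")

    def _probe(s):
        strand = make_strand(length_mm=40.0, h=h, sigma=float(s),
                             along_fibers=(direction == "L"), model=model)
        return measure_cv(strand, (1, 0, 0), dt=dt)

    if probe_sigmas is None:
        # upper probe bounded by explicit-diffusion stability at (h, dt)
        s_top = 0.45 if direction == "L" else 0.22
        coarse = np.geomspace(0.004, s_top, 7)
        scan = []
        for s in coarse:
            try:
                scan.append((float(s), _probe(s)))
            except PropagationFailureError:
                continue  # below the propagation limit
        if len(scan) < 2:
            raise RuntimeError("fewer than 2 coarse probes sustained propagation")
        cv_lo, cv_hi = scan[0][1], scan[-1][1]
        if not (cv_lo <= target_cv <= cv_hi):
            raise ValueError(
                f"target CV {target_cv} mm/ms outside achievable range "
                f"[{cv_lo:.3f}, {cv_hi:.3f}]"
            )
        k = next(i for i in range(len(scan) - 1) if scan[i + 1][1] >= target_cv)
        s_lo, s_hi = scan[k][0], scan[k + 1][0]
        probe_sigmas = np.geomspace(s_lo / 1.1, s_hi * 1.1, 5)
    sigmas, cvs = [], []
    for s in probe_sigmas:
        try:
            cv = _probe(s)
        except PropagationFailureError:
            continue
        sigmas.append(float(s))
        cvs.append(cv)
    if len(sigmas) < 4:
        raise RuntimeError("fewer than 4 probe conductivities sustained propagation")
    if not (min(cvs) <= target_cv <= max(cvs)):
        raise ValueError(
            f"target CV {target_cv} mm/ms outside bracketed range "
            f"[{min(cvs):.3f}, {max(cvs):.3f}]"
        )
    x = np.log(np.asarray(sigmas))
    y = np.asarray(cvs)
    a, b = np.polyfit(x, y, 1)
    fit = a * x + b
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sigma_star = float(np.exp((target_cv - b) / a))
    return CalibrationResult(
        sigma=sigma_star, target_cv=float(target_cv), slope=float(a),
        intercept=float(b), r_squared=r2, probe_sigmas=tuple(sigmas),
        probe_cvs=tuple(cvs), residuals=tuple(float(r) for r in (y - fit)),
    )
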