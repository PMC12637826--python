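"""Single-cell ionic models for the three tissue phenotypes.

The baseline ("GE", gene-elusive) myocyte is a ten Tusscher–Panfilov 2006
epicardial cell with an added late sodium current.  Its repolarizing
conductances are calibrated (package constants ``BASE_G_KR/BASE_G_KS``)
so that the steady action-potential duration at a 600-ms drive-train cycle
length sits near the human epicardial range (~230 ms), which keeps the
clinical extrastimulus coupling range (250 ms and below) physiologically
meaningful.

Two remodeled phenotypes are expressed as conductance scale factors on the
baseline:

``PKP2``
    plakophilin-2 loss-of-function: reduced fast sodium current (slower
    upstroke, lower peak), reduced inward-rectifier IK1 (depolarized
    resting potential), reduced L-type calcium current (flattened APD
    restitution).
``FIB``
    diffuse-fibrosis remodeling (non-ischemic-cardiomyopathy style):
    reduced INa, ICaL and repolarizing K currents, giving a longer action
    potential and slower conduction.

The exact remodeling magnitudes are package defaults chosen to satisfy the
qualitative electrophysiological contrasts above; they are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tt2
from ._tt2 import N_SCALES, N_STATE, SCALE_NAMES, STATE_NAMES, build_tables, no_diffusion

__all__ = [
    "IonicModelParams",
    "CellState",
    "APFeatures",
    "NoCaptureError",
    "NumericalInstabilityError",
    "PHENOTYPES",
    "step_cell",
    "simulate_ap",
    "restitution_curve",
]

# Repolarization calibration of the baseline epicardial cell (package
# constants: IKr x3.2, IKs x3.0 relative to the published set), placing
# APD90 at a 600-ms cycle length near 195 ms so the programmed-stimulation
# coupling scan (250 ms and below) straddles the capture boundary, as it
# does clinically.
BASE_SCALES = {"g_Kr": 3.2, "g_Ks": 3.0}

PHENOTYPES = {
    "GE": {},
    "PKP2": {"g_Na": 0.35, "g_K1": 0.40, "g_CaL": 0.70},
    "FIB": {"g_Na": 0.40, "g_CaL": 0.65, "g_Kr": 0.45, "g_Ks": 0.40, "g_to": 0.70},
}


class NoCaptureError(RuntimeError):
    """Raised when a stimulus fails to elicit a propagated action potential."""


class NumericalInstabilityError(RuntimeError):
    """Raised when the integrator produces a non-finite state variable."""


@dataclass(frozen=True)
class IonicModelParams:
    """Conductance scaling of the baseline cell for one tissue phenotype.

    Parameters
    ----------
    phenotype
        One of ``"GE"``, ``"PKP2"``, ``"FIB"`` (or a custom tag).
    scales
        Per-current multipliers relative to the GE baseline.  Keys from
        ``SCALE_NAMES``; missing keys default to 1.
    g_NaL_scale
        Late-sodium conductance multiplier (1 = enabled at baseline level).
    rmp_shift_target_mv
        Informational target for the resting-potential shift of remodeled
        phenotypes; not enforced, validated by tests.
    """

    phenotype: str = "GE"
    scales: dict = field(default_factory=dict)
    g_NaL_scale: float = 1.0
    rmp_shift_target_mv: float = 0.0

    def __post_init__(self):
        for k, v in self.scales.items():
            if k not in SCALE_NAMES:
                raise ValueError(f"unknown conductance scale {k!r}")
            if v < 0:
                raise ValueError(f"scale factor {k!r} must be >= 0, got {v}")
        if self.g_NaL_scale < 0:
            raise ValueError("g_NaL_scale must be >= 0")

    @classmethod
    def for_phenotype(cls, phenotype: str, **overrides) -> "IonicModelParams":
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}; choose from {sorted(PHENOTYPES)}")
        scales = dict(PHENOTYPES[phenotype])
        scales.update(overrides.pop("scales", {}))
        return cls(phenotype=phenotype, scales=scales, **overrides)

    def to_json(self) -> str:
        import json

        return json.dumps({
            "phenotype": self.phenotype, "scales": self.scales,
            "g_NaL_scale": self.g_NaL_scale,
            "rmp_shift_target_mv": self.rmp_shift_target_mv,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IonicModelParams":
        import json

        return cls(**json.loads(text))

    def scale_row(self) -> np.ndarray:
        """Scale factors as a row vector in kernel column order."""
        row = np.ones(N_SCALES)
        merged = dict(BASE_SCALES)
        for k, v in self.scales.items():
            merged[k] = merged.get(k, 1.0) * v
        for j, name in enumerate(SCALE_NAMES):
            if name in merged:
                row[j] = merged[name]
        row[SCALE_NAMES.index("g_NaL")] *= self.g_NaL_scale
        return row


@dataclass
class CellState:
    """Full ionic state vector of one cell."""

    values: np.ndarray  # (N_STATE,) in STATE_NAMES order

    @classmethod
    def resting(cls) -> "CellState":
        return cls(values=_tt2.resting_state())

    @property
    def vm(self) -> float:
        return float(self.values[0])

    def __getitem__(self, name: str) -> float:
        return float(self.values[STATE_NAMES.index(name)])

    def check(self) -> None:
        if not np.all(np.isfinite(self.values)):
            bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise NumericalInstabilityError(f"non-finite state variable(s): {', '.join(bad)}")
        gates = self.values[1:16]
        if np.any(gates < -1e-9) or np.any(gates > 1 + 1e-9):
            raise NumericalInstabilityError("gating variable out of [0, 1]")
        if np.any(self.values[16:21] <= 0):
            raise NumericalInstabilityError("non-positive ionic concentration")


@dataclass(frozen=True)
class APFeatures:
    """Action-potential phenotype of a paced beat."""

    rmp_mv: float
    peak_mv: float
    dvdt_max: float       # mV/ms
    apd90_ms: float
    t_upstroke_ms: float  # time of dVdt_max relative to stimulus onset


_TABLE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def tables_for(dt: float) -> tuple[np.ndarray, np.ndarray]:
    key = round(float(dt), 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = build_tables(key)
    return _TABLE_CACHE[key]


def _run_cell(state_vec, params, dt, t0, duration, stim_times, stim_amp, stim_dur,
              sample_every_ms=0.1):
    """Drive a single cell; returns (t vector, Vm trace) sampled uniformly."""
    n_steps = int(round(duration / dt))
    scales = params.scale_row()[None, :]
    phen = np.zeros(1, dtype=np.int8)
    tab, k1tab = tables_for(dt)
    wp, wi, wx = no_diffusion(1)
    stim_times = np.asarray(stim_times, dtype=np.float64)
    n_stim = stim_times.size
    stim_start = stim_times
    stim_durs = np.full(n_stim, stim_dur)
    stim_amps = np.full(n_stim, stim_amp)
    stim_ptr = np.arange(n_stim + 1, dtype=np.int64)
    stim_idx = np.zeros(n_stim, dtype=np.int64)
    e_rev = np.zeros((1, 4))
    last_cross = np.full(1, -1.0)
    armed = np.ones(1, dtype=np.int8)
    cap = 1024
    ev_node = np.zeros(cap, dtype=np.int64)
    ev_time = np.zeros(cap)
    ev_count = np.zeros(1, dtype=np.int64)
    sample_every = max(1, int(round(sample_every_ms / dt)))
    n_samp = n_steps // sample_every
    sample_buf = np.empty((n_samp, 1))
    diff_scratch = np.zeros(1)
    state = state_vec.reshape(1, -1)
    t_end, status = _tt2.run_chunk(
        state, phen, scales, tab, k1tab, wp, wi, wx, dt, t0, n_steps,
        stim_start, stim_durs, stim_amps, stim_ptr, stim_idx,
        e_rev, 10, last_cross, armed, ev_node, ev_time, ev_count,
        sample_buf, sample_every, diff_scratch, -1.0,
    )
    if status == 2:
        raise NumericalInstabilityError("membrane potential left [-200, 200] mV")
    t = t0 + dt * sample_every * (1 + np.arange(n_samp))
    return t, sample_buf[:, 0]


DEFAULT_DT = 0.02          # ms, fixed-step Rush-Larsen integration
STIM_AMP = 52.0            # pA/pF (~2x diastolic threshold), 2-ms pulse
STIM_DUR = 2.0


def step_cell(state: CellState, params: IonicModelParams, dt: float,
              i_stim: float = 0.0) -> CellState:
    """One forward step (Rush–Larsen gates, explicit Euler otherwise).

    ``i_stim`` is a depolarizing current density in pA/pF (positive
    depolarizes).  ``dt`` must lie in (0, 0.05] ms.
    """
    if not (0.0 < dt <= 0.05):
        raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
    vec = state.values.copy()
    scales = params.scale_row()[None, :]
    phen = np.zeros(1, dtype=np.int8)
    tab, k1tab = tables_for(dt)
    wp, wi, wx = no_diffusion(1)
    stim_start = np.zeros(1)
    stim_durs = np.full(1, dt)
    stim_amps = np.full(1, i_stim)
    stim_ptr = np.array([0, 1], dtype=np.int64)
    stim_idx = np.zeros(1, dtype=np.int64)
    e_rev = np.zeros((1, 4))
    s2 = vec.reshape(1, -1)
    _tt2.run_chunk(
        s2, phen, scales, tab, k1tab, wp, wi, wx, dt, 0.0, 1,
        stim_start, stim_durs, stim_amps, stim_ptr, stim_idx,
        e_rev, 1, np.full(1, -1.0), np.ones(1, dtype=np.int8),
        np.zeros(4, dtype=np.int64), np.zeros(4), np.zeros(1, dtype=np.int64),
        np.empty((0, 1)), 0, np.zeros(1), -1.0,
    )
    out = CellState(values=vec)
    out.check()
    return out


def _extract_features(t, vm, stim_onset) -> APFeatures:
    """AP features of the beat triggered at ``stim_onset`` (same time base)."""
    pre = vm[(t >= stim_onset - 20.0) & (t < stim_onset)]
    if pre.size == 0:
        pre = vm[:1]
    rmp = float(pre.min())
    sel = t >= stim_onset
    tb, vb = t[sel], vm[sel]
    dvdt = np.diff(vb) / np.diff(tb)
    k = int(np.argmax(dvdt[: min(dvdt.size, int(50 / (tb[1] - tb[0])))]))
    dvdt_max = float(dvdt[k])
    t_up = float(tb[k + 1])
    peak = float(vb.max())
    if peak < -20.0 or dvdt_max < 1.0:
        raise NoCaptureError(
            f"no action potential elicited (peak {peak:.1f} mV, dVdt {dvdt_max:.2f} mV/ms)"
        )
    v90 = rmp + 0.1 * (peak - rmp)
    after = np.flatnonzero((vb[:-1] >= v90) & (vb[1:] < v90) & (tb[1:] > t_up))
    if after.size == 0:
        raise NoCaptureError("action potential did not repolarize to 90% within the window")
    i9 = after[0]
    # linear interpolation of the crossing time
    frac = (vb[i9] - v90) / (vb[i9] - vb[i9 + 1])
    t90 = tb[i9] + frac * (tb[i9 + 1] - tb[i9])
    return APFeatures(
        rmp_mv=rmp, peak_mv=peak, dvdt_max=dvdt_max,
        apd90_ms=float(t90 - t_up), t_upstroke_ms=float(t_up - stim_onset),
    )


def paced_state(params: IonicModelParams, pacing_cl: float, n_beats: int,
                dt: float = DEFAULT_DT) -> np.ndarray:
    """State vector after ``n_beats`` of pacing (end-diastole of last cycle)."""
    vec = _tt2.resting_state()
    stim_times = pacing_cl * np.arange(n_beats)
    _run_cell(vec, params, dt, 0.0, pacing_cl * n_beats - 5.0, stim_times,
              STIM_AMP, STIM_DUR, sample_every_ms=1.0)
    return vec


def simulate_ap(params: IonicModelParams, pacing_cl: float = 600.0,
                n_beats: int = 8, dt: float = DEFAULT_DT) -> APFeatures:
    """Features of the last of ``n_beats`` paced action potentials."""
    if n_beats < 5:
        raise ValueError("n_beats must be >= 5 (pre-pacing to the limit cycle)")
    vec = _tt2.resting_state()
    stim_times = pacing_cl * np.arange(n_beats)
    last = stim_times[-1]
    t, vm = _run_cell(vec, params, dt, 0.0, pacing_cl * n_beats, stim_times,
                      STIM_AMP, STIM_DUR, sample_every_ms=0.05)
    return _extract_features(t, vm, last)


def ap_trace(params: IonicModelParams, pacing_cl: float = 600.0,
             n_beats: int = 6, dt: float = DEFAULT_DT,
             sample_every_ms: float = 0.1):
    """Time base and membrane potential of a paced run (for export)."""
    vec = _tt2.resting_state()
    stim_times = pacing_cl * np.arange(n_beats)
    return _run_cell(vec, params, dt, 0.0, pacing_cl * n_beats, stim_times,
                     STIM_AMP, STIM_DUR, sample_every_ms=sample_every_ms)


def write_ap_csv(path, t_ms: np.ndarray, vm_mv: np.ndarray) -> None:
    """AP trace as a two-column CSV (t_ms, Vm_mV)."""
    import pandas as pd

    pd.DataFrame({"t_ms": t_ms, "Vm_mV": vm_mv}).to_csv(path, index=False)


def restitution_curve(params: IonicModelParams, s1_cl: float = 600.0,
                      di_list=(40, 60, 80, 100, 150, 200, 300, 400),
                      n_beats: int = 8, dt: float = DEFAULT_DT):
    """S1–S2 restitution: APD90 of a premature beat vs diastolic interval.

    Returns ``(points, max_slope)`` where ``points`` is a list of
    ``(di_ms, apd90_ms or None)`` (None = loss of capture, excluded from
    the slope) and ``max_slope`` the maximum finite-difference slope of
    the captured branch.
    """
    di_arr = np.asarray(sorted(di_list), dtype=np.float64)
    if np.any(di_arr <= 0):
        raise ValueError("all diastolic intervals must be > 0")
    base = paced_state(params, s1_cl, n_beats, dt)
    s1_feat = simulate_ap(params, s1_cl, n_beats, dt)
    # time of 90% repolarization of the last S1 beat, relative to cycle start
    t_repol = s1_feat.t_upstroke_ms + s1_feat.apd90_ms
    points = []
    for di in di_arr:
        vec = base.copy()
        t0 = s1_cl * (n_beats - 1) - 5.0
        s2_time = s1_cl * (n_beats - 1) + t_repol + di
        t, vm = _run_cell(vec, params, dt, t0, (s2_time - t0) + 600.0,
                          [s1_cl * (n_beats - 1), s2_time], STIM_AMP, STIM_DUR,
                          sample_every_ms=0.05)
        try:
            feat = _extract_features(t, vm, s2_time)
            points.append((float(di), feat.apd90_ms))
        except NoCaptureError:
            points.append((float(di), None))
    captured = [(d, a) for d, a in points if a is not None]
    max_slope = 0.0
    for (d0, a0), (d1, a1) in zip(captured, captured[1:]):
        slope = (a1 - a0) / (d1 - d0)
        max_slope = max(max_slope, slope)
    return points, float(max_slope)
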