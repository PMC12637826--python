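"""Programmed stimulation: protocol schedule, site selection, sustained
reentry detection and morphology deduplication."""

import numpy as np
import pytest

from vtwin.imaging import partition_aha
from vtwin.induction import (
    PacingProtocol,
    VTEpisode,
    dedupe_morphologies,
    detect_sustained,
    run_protocol,
    select_pacing_sites,
)
from vtwin.labels import SCAR
from vtwin.tissue import make_sheet


def test_coupling_scan_is_250_down_to_180_by_10():
    proto = PacingProtocol()
    assert proto.couplings == tuple(float(c) for c in range(250, 179, -10))


def test_protocol_validation():
    with pytest.raises(ValueError, match="decrement"):
        PacingProtocol(decrement=0)
    with pytest.raises(ValueError, match="cycle length"):
        PacingProtocol(s2_initial=700.0)
    with pytest.raises(ValueError, match="extrastimuli"):
        PacingProtocol(max_extrastimuli=5)


# ---------------------------------------------------------- site selection

def test_nine_sites_one_per_segment():
    dom = make_sheet(45, 45)
    aha = partition_aha(dom.shape, dom.tissue != 0)
    sites = select_pacing_sites(aha, dom)
    assert len(sites) == 9
    seg_of = []
    for x, y, _ in sites:
        iy, ix = int(round(y / dom.h)), int(round(x / dom.h))
        seg_of.append(aha.segment[iy, ix])
    assert sorted(seg_of) == list(range(9))


def test_scarred_segment_is_skipped(caplog):
    dom = make_sheet(45, 45)
    seg_mask = partition_aha(dom.shape, dom.tissue != 0).segment == 0
    dom.tissue[seg_mask] = SCAR
    aha = partition_aha(dom.shape, dom.tissue != 0)
    with caplog.at_level("WARNING"):
        sites = select_pacing_sites(aha, dom)
    assert len(sites) == 8
    assert "no conducting surface node" in caplog.text


def test_site_matches_brute_force_argmin():
    dom = make_sheet(33, 33)
    dom.tissue[2:9, 2:9] = SCAR
    aha = partition_aha(dom.shape, dom.tissue != 0)
    sites = select_pacing_sites(aha, dom)
    for k, site in enumerate(sites):
        seg_nodes = np.flatnonzero((aha.segment == k).ravel())
        centroid = dom.node_xyz(seg_nodes).mean(axis=0)
        cand = seg_nodes[dom.conducting.ravel()[seg_nodes]]
        xyz = dom.node_xyz(cand)
        best = cand[np.argmin(((xyz - centroid) ** 2).sum(axis=1))]
        np.testing.assert_allclose(site, dom.node_xyz(np.array([best]))[0])


# ------------------------------------------------------ sustained detection

def _spiral_events(domain, center, cl, n_cycles, pitch_ms_per_mm=8.0):
    """Crossing events of an Archimedean-spiral activation rotating about
    ``center``: LAT = (theta/2pi)*CL + r*pitch, repeated every cycle."""
    cond = np.flatnonzero(domain.conducting.ravel())
    xyz = domain.node_xyz(cond)
    rel = xyz - np.asarray(center)
    theta = np.arctan2(rel[:, 1], rel[:, 0]) % (2 * np.pi)
    r = np.hypot(rel[:, 0], rel[:, 1])
    phase = (theta / (2 * np.pi) * cl + r * pitch_ms_per_mm) % cl
    nodes, times = [], []
    for k in range(n_cycles):
        nodes.append(cond)
        times.append(100.0 + phase + k * cl)
    nodes = np.concatenate(nodes)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return nodes[order], times[order]


def test_constructed_spiral_detected_with_core_at_center():
    dom = make_sheet(80, 80)
    center = (9.0, 11.0, 0.0)
    nodes, times = _spiral_events(dom, center, cl=300.0, n_cycles=4)
    ep = detect_sustained(nodes, times, dom, t_final_stim=50.0)
    assert ep is not None
    assert ep.cycle_length_ms == pytest.approx(300.0, abs=5.0)
    assert ep.duration_cycles >= 2
    core = ep.core_trajectory.mean(axis=0)
    assert np.linalg.norm(core[:2] - np.array(center[:2])) <= 2.0


def test_single_cycle_not_sustained():
    dom = make_sheet(80, 80)
    nodes, times = _spiral_events(dom, (10.0, 10.0, 0.0), cl=300.0, n_cycles=2)
    # two passes = one re-excitation = one full cycle only
    ep = detect_sustained(nodes, times, dom, t_final_stim=50.0)
    assert ep is None


def test_paced_beat_that_extinguishes_is_not_sustained():
    dom = make_sheet(60, 60)
    cond = np.flatnonzero(dom.conducting.ravel())
    xyz = dom.node_xyz(cond)
    times = 60.0 + np.hypot(xyz[:, 0] - 1, xyz[:, 1] - 1) / 0.4  # one sweep
    order = np.argsort(times)
    ep = detect_sustained(cond[order], times[order], dom, t_final_stim=50.0)
    assert ep is None


def test_chirality_distinguishes_rotation_sense():
    dom = make_sheet(80, 80)
    center = (10.0, 10.0, 0.0)
    nodes, times = _spiral_events(dom, center, cl=300.0, n_cycles=4)
    ep_ccw = detect_sustained(nodes, times, dom, t_final_stim=50.0)
    # mirror x to flip the rotation sense
    cond = np.flatnonzero(dom.conducting.ravel())
    xyz = dom.node_xyz(cond)
    extent = (dom.shape[1] - 1) * dom.h
    mirror = {n: None for n in cond}
    ix = np.round(xyz[:, 0] / dom.h).astype(int)
    iy = np.round(xyz[:, 1] / dom.h).astype(int)
    flipped = iy * dom.shape[1] + (dom.shape[1] - 1 - ix)
    lut = dict(zip(cond, flipped))
    nodes_m = np.array([lut[n] for n in nodes])
    ep_cw = detect_sustained(nodes_m, times, dom, t_final_stim=50.0)
    assert ep_ccw is not None and ep_cw is not None
    assert ep_ccw.chirality == -ep_cw.chirality


# ------------------------------------------------------------- protocol e2e

def test_healthy_sheet_is_non_inducible(healthy_sheet, reduced_protocol):
    eps = run_protocol(healthy_sheet, reduced_protocol)
    assert eps == []


def test_channel_fixture_induces_sustained_reentry(episode1):
    assert episode1.duration_cycles >= 2
    assert episode1.cycle_length_ms > 0
    assert len(episode1.couplings) >= 1
    assert np.isfinite(episode1.lat_cycle).sum() > 100


def test_protocol_is_deterministic(domain1, reduced_protocol, episode1):
    eps = run_protocol(domain1, reduced_protocol)
    assert eps
    assert eps[0].couplings == episode1.couplings
    assert eps[0].cycle_length_ms == pytest.approx(episode1.cycle_length_ms)
    np.testing.assert_allclose(eps[0].core_trajectory, episode1.core_trajectory)


# ------------------------------------------------------------------ dedupe

def _fake_episode(core, cl, chir):
    return VTEpisode(
        site=(0, 0, 0), site_index=0, couplings=(250.0,), cycle_length_ms=cl,
        core_trajectory=np.array([core]), chirality=chir, duration_cycles=2,
        t_final_stim=0.0, cycle_window=(0.0, cl), lat_cycle=np.zeros((2, 2)),
    )


def test_dedupe_merges_same_segment_cl_chirality():
    dom = make_sheet(45, 45)
    aha = partition_aha(dom.shape, dom.tissue != 0)
    a = _fake_episode((2.0, 2.0, 0.0), 300.0, 1)
    b = _fake_episode((3.0, 3.0, 0.0), 305.0, 1)   # same segment, CL within 10
    assert len(dedupe_morphologies([a, b], aha, h=dom.h)) == 1


def test_dedupe_keeps_opposite_chirality():
    dom = make_sheet(45, 45)
    aha = partition_aha(dom.shape, dom.tissue != 0)
    a = _fake_episode((2.0, 2.0, 0.0), 300.0, 1)
    b = _fake_episode((2.0, 2.0, 0.0), 300.0, -1)
    assert len(dedupe_morphologies([a, b], aha, h=dom.h)) == 2


def test_dedupe_matches_brute_force_partition(rng):
    dom = make_sheet(45, 45)
    aha = partition_aha(dom.shape, dom.tissue != 0)
    eps = [
        _fake_episode((rng.uniform(0, 11), rng.uniform(0, 11), 0.0),
                      rng.choice([290.0, 320.0, 350.0]), rng.choice([-1, 1]))
        for _ in range(20)
    ]

    def same(e1, e2):
        s1 = e1.morphology_signature(aha, dom.h)
        s2 = e2.morphology_signature(aha, dom.h)
        return (s1[0] == s2[0] and abs(e1.cycle_length_ms - e2.cycle_length_ms) <= 10
                and e1.chirality == e2.chirality)

    brute = []
    for e in eps:
        if not any(same(e, u) for u in brute):
            brute.append(e)
    ours = dedupe_morphologies(eps, aha, h=dom.h)
    assert len(ours) == len(brute)
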