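"""Virtual ablation planning: minimal lesion sets that render the
substrate non-inducible.

The planner runs the programmed-stimulation protocol over the pacing
sites, targets the critical isthmus of the first sustained episode with
a 3,500-um-radius insulating lesion (falling back to the reentry-core
medoid when no corridor is found), joins adjacent lesions with a line
lesion when an iatrogenic circuit threads between them, and repeats the
full protocol until no site induces VT.  A leave-one-out audit reports
which spot lesions are individually necessary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .circuits import NoIsthmusError, identify_isthmus, isochrone_decompose
from .imaging import partition_aha
from .induction import PacingProtocol, VTEpisode, run_protocol, select_pacing_sites
from .tissue import DEFAULT_DT, TissueDomain

log = logging.getLogger(__name__)

__all__ = [
    "Lesion",
    "LesionSet",
    "PlannerResult",
    "apply_lesion",
    "plan",
    "lesion_minimality_report",
    "PlannerFailure",
]

LESION_RADIUS_MM = 3.5  # 3,500-um ablation-catheter lesion radius


class PlannerFailure(RuntimeError):
    """Planner exceeded max_rounds; partial lesion set attached."""

    def __init__(self, msg, result):
        super().__init__(msg)
        self.result = result


@dataclass(frozen=True)
class Lesion:
    """A spot (sphere/disc) or line (capsule) insulating lesion."""

    center: tuple
    radius_mm: float = LESION_RADIUS_MM
    kind: str = "spot"               # "spot" | "line"
    endpoint: tuple | None = None    # second capsule endpoint for lines

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.kind not in ("spot", "line"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "line" and self.endpoint is None:
            raise ValueError("line lesion requires an endpoint")


@dataclass
class LesionSet:
    """Ordered lesions with provenance (which episode each one targeted)."""

    lesions: list = field(default_factory=list)
    provenance: list = field(default_factory=list)   # dicts per lesion
    total_nodes: int = 0

    def add(self, lesion: Lesion, provenance: dict, n_nodes: int):
        self.lesions.append(lesion)
        self.provenance.append(provenance)
        self.total_nodes += n_nodes

    @property
    def spots(self):
        return [l for l in self.lesions if l.kind == "spot"]

    def __len__(self):
        return len(self.lesions)


def apply_lesion(domain: TissueDomain, lesion: Lesion) -> TissueDomain:
    """Insulate all nodes within the lesion (idempotent; returns a copy).

    Spot: Euclidean ball of ``radius_mm`` around the center.  Line:
    capsule of the same radius around the center-endpoint segment.
    """
    out = domain.copy()
    coords = out.node_xyz(np.arange(out.tissue.size))
    a = np.asarray((list(lesion.center) + [0.0])[:3], dtype=float)
    if lesion.kind == "spot":
        d = np.linalg.norm(coords - a, axis=1)
    else:
        b = np.asarray((list(lesion.endpoint) + [0.0])[:3], dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((coords - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        d = np.linalg.norm(coords - (a + np.outer(t, ab)), axis=1)
    inside = (d <= lesion.radius_mm).reshape(out.shape)
    if not inside.any():  # degenerate radius: nearest node only
        inside.ravel()[int(np.argmin(d))] = True
    out.lesion |= inside
    return out


@dataclass
class PlannerResult:
    lesions: LesionSet
    final_domain: TissueDomain
    non_inducible: bool
    rounds: int
    audit_log: list


def _relocate_site(domain: TissueDomain, site) -> tuple | None:
    """Nearest conducting node to a site that ablation has insulated."""
    cond = np.flatnonzero(domain.conducting.ravel())
    if cond.size == 0:
        return None
    xyz = domain.node_xyz(cond)
    p = np.asarray((list(site) + [0.0])[:3], dtype=float)
    return tuple(float(v) for v in xyz[int(np.argmin(((xyz - p) ** 2).sum(axis=1)))])


def _first_episode(domain: TissueDomain, sites, base_protocol: PacingProtocol,
                   dt: float) -> VTEpisode | None:
    """First sustained episode in site order (couplings scanned within
    run_protocol longest-first; the first site that induces wins)."""
    for idx, site in enumerate(sites):
        log.info("pacing protocol: site %d of %d", idx + 1, len(sites))
        site = tuple(site)
        if not domain.conducting[domain.nearest_node(site)]:
            moved = _relocate_site(domain, site)
            log.warning("pacing site %d at %s is insulated; moved to %s",
                        idx, site, moved)
            if moved is None:
                continue
            site = moved
        proto = replace(base_protocol, site=site)
        eps = run_protocol(domain, proto, dt=dt, site_index=idx)
        if eps:
            return eps[0]
    return None


def _verify_non_inducible(domain, sites, base_protocol, dt) -> bool:
    return _first_episode(domain, sites, base_protocol, dt) is None


def _target_for(episode: VTEpisode, domain: TissueDomain,
                corridor_halfwidth_mm: float):
    iso = isochrone_decompose(episode.lat_cycle, episode.cycle_length_ms)
    try:
        nodes, center = identify_isthmus(
            iso, domain, episode, corridor_halfwidth_mm=corridor_halfwidth_mm
        )
        return center, "isthmus"
    except NoIsthmusError:
        traj = np.atleast_2d(episode.core_trajectory)
        d = np.linalg.norm(traj[:, None, :] - traj[None, :, :], axis=2).sum(axis=1)
        medoid = traj[int(np.argmin(d))]
        return tuple(float(v) for v in medoid), "core_medoid"


def _crosses_between(episode: VTEpisode, a, b, radius_mm: float) -> bool:
    """Does the episode's core path pass between lesion centers a and b?"""
    traj = np.atleast_2d(episode.core_trajectory)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return False
    t = (traj - a) @ ab / denom
    d = np.linalg.norm(traj - (a + np.outer(np.clip(t, 0, 1), ab)), axis=1)
    return bool(np.any((t > 0.05) & (t < 0.95) & (d <= radius_mm)))


def plan(domain: TissueDomain, base_protocol: PacingProtocol | None = None,
         sites: list | None = None, dt: float = DEFAULT_DT,
         lesion_radius_mm: float = LESION_RADIUS_MM,
         connect_threshold_mm: float = 10.0,
         corridor_halfwidth_mm: float = 4.0,
         max_rounds: int = 20) -> PlannerResult:
    """Iterate induce -> ablate until the domain is non-inducible.

    Each round runs the pacing protocol over the sites in order, targets
    the first sustained episode's isthmus center with a spot lesion, and
    adds a line lesion joining two existing lesions when the episode's
    core path runs between lesions closer than ``connect_threshold_mm``.
    Raises :class:`PlannerFailure` (with the partial result attached)
    after ``max_rounds``.
    """
    base_protocol = base_protocol or PacingProtocol()
    if sites is None:
        aha = partition_aha(domain.shape, domain.tissue != 0)
        sites = select_pacing_sites(aha, domain)
    if not sites:
        raise ValueError("no pacing sites available")
    lesions = LesionSet()
    audit = []
    current = domain
    for rnd in range(1, max_rounds + 1):
        episode = _first_episode(current, sites, base_protocol, dt)
        if episode is None:
            audit.append({"round": rnd, "episode": None, "action": "stop: non-inducible"})
            return PlannerResult(lesions=lesions, final_domain=current,
                                 non_inducible=True, rounds=rnd, audit_log=audit)
        prev_nodes = int(current.lesion.sum())
        added = []
        # line connection first: an iatrogenic circuit threading between
        # two existing lesions gets a connecting line lesion
        lined = False
        if len(lesions.spots) >= 2:
            spots = lesions.spots
            for i in range(len(spots)):
                for j in range(i + 1, len(spots)):
                    a, b = spots[i].center, spots[j].center
                    gap = float(np.linalg.norm(np.subtract(a, b)))
                    if gap <= connect_threshold_mm and _crosses_between(
                        episode, a, b, connect_threshold_mm / 2.0
                    ):
                        les = Lesion(center=a, endpoint=b, kind="line",
                                     radius_mm=lesion_radius_mm)
                        current = apply_lesion(current, les)
                        n_new = int(current.lesion.sum()) - prev_nodes
                        lesions.add(les, {
                            "round": rnd, "site_index": episode.site_index,
                            "couplings": episode.couplings, "target_kind": "line_connection",
                            "cycle_length_ms": episode.cycle_length_ms,
                        }, n_new)
                        added.append(("line", a, b))
                        lined = True
                        break
                if lined:
                    break
        if not lined:
            center, kind = _target_for(episode, current, corridor_halfwidth_mm)
            les = Lesion(center=center, radius_mm=lesion_radius_mm, kind="spot")
            current = apply_lesion(current, les)
            n_new = int(current.lesion.sum()) - prev_nodes
            lesions.add(les, {
                "round": rnd, "site_index": episode.site_index,
                "couplings": episode.couplings, "target_kind": kind,
                "cycle_length_ms": episode.cycle_length_ms,
            }, n_new)
            added.append(("spot", center))
        audit.append({
            "round": rnd,
            "episode": {
                "site_index": episode.site_index,
                "couplings": list(episode.couplings),
                "cycle_length_ms": episode.cycle_length_ms,
                "chirality": episode.chirality,
                "core": [float(v) for v in episode.core],
            },
            "action": added,
            "lesioned_nodes_total": int(current.lesion.sum()),
        })
    result = PlannerResult(lesions=lesions, final_domain=current,
                           non_inducible=False, rounds=max_rounds, audit_log=audit)
    raise PlannerFailure(f"still inducible after {max_rounds} rounds", result)


def lesion_minimality_report(domain: TissueDomain, lesions: LesionSet,
                             base_protocol: PacingProtocol | None = None,
                             sites: list | None = None,
                             dt: float = DEFAULT_DT) -> list:
    """Leave-one-out necessity audit of the spot lesions.

    For each spot lesion, re-apply all other lesions to the original
    domain and re-run the protocol; the lesion is necessary iff VT
    becomes inducible without it.  Returns one record per spot lesion.
    """
    base_protocol = base_protocol or PacingProtocol()
    if sites is None:
        aha = partition_aha(domain.shape, domain.tissue != 0)
        sites = select_pacing_sites(aha, domain)
    report = []
    spot_idx = [i for i, l in enumerate(lesions.lesions) if l.kind == "spot"]
    for i in spot_idx:
        reduced = domain
        for j, les in enumerate(lesions.lesions):
            if j != i:
                reduced = apply_lesion(reduced, les)
        inducible = not _verify_non_inducible(reduced, sites, base_protocol, dt)
        report.append({
            "lesion_index": i,
            "center": lesions.lesions[i].center,
            "necessary": inducible,
        })
    return report
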