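"""Shared fixtures.

Expensive simulation products (the induced episode and the full ablation
plan on the bundled channel fixture) are session-scoped so the induction,
circuit-analysis, planner and acceptance tests share one computation.
"""

import numpy as np
import pytest

from vtwin.imaging import classify_tissue, partition_aha, resample_isotropic
from vtwin.induction import PacingProtocol, run_protocol, select_pacing_sites
from vtwin.pipeline import build_domain
from vtwin.planner import plan
from vtwin.synthetic import GeneratorParams, generate_patient

CORNER_SITE = (2.0, 2.0, 0.0)  # adjacent to the default channel's far mouth


@pytest.fixture(scope="session")
def patient1():
    return generate_patient(seed=1)


@pytest.fixture(scope="session")
def domain1(patient1):
    seg = classify_tissue(resample_isotropic(patient1.intensity, 0.35))
    return build_domain(seg, genotype="PKP2")


@pytest.fixture(scope="session")
def sites1(domain1):
    aha = partition_aha(domain1.shape, domain1.tissue != 0)
    return select_pacing_sites(aha, domain1)


@pytest.fixture(scope="session")
def reduced_protocol():
    """Two drive beats from the paced limit cycle; same extrastimulus scan."""
    return PacingProtocol(site=CORNER_SITE, n_s1=2, paced_init=True)


@pytest.fixture(scope="session")
def episode1(domain1, reduced_protocol):
    """One sustained reentry on the bundled fixture (reduced drive)."""
    eps = run_protocol(domain1, reduced_protocol)
    assert eps, "fixture substrate failed to induce"
    return eps[0]


@pytest.fixture(scope="session")
def plan_full(domain1, sites1):
    """Full-protocol ablation plan on the bundled fixture (six S1 beats,
    S2-S5 scans, all nine sites re-tested after each round)."""
    return plan(domain1, base_protocol=PacingProtocol(), sites=sites1)


@pytest.fixture(scope="session")
def healthy_sheet():
    """Channel-free control patient: uniform conducting sheet (built from
    truth labels; a substrate-free image has no bimodal histogram)."""
    params = GeneratorParams(channel_count=0, channel_x_mm=(),
                             fibrosis_fraction=0.0, extent_mm=14.0)
    p = generate_patient(params, seed=7)
    return build_domain(p.truth_labels, genotype="PKP2")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
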