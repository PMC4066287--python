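"""Shared fixtures: one small simulated study pair reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eqtloverlap as eo
from eqtloverlap.pipeline import map_study

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


SMALL_CONFIG = eo.SimulationConfig(
    n_genes=300, n_individuals_i=400, n_individuals_j=150, pi_true=0.3,
    n_haplotypes=800, seed=11)


@pytest.fixture(scope="session")
def sim_bundle():
    """Panel, raw pair, truth and mapped studies for a small default-style run."""
    cfg = SMALL_CONFIG
    panel = eo.simulate_haplotype_panel(cfg)
    raw_i, raw_j, truth = eo.simulate_study_pair(panel, cfg)
    study_i = map_study(raw_i)
    study_j = map_study(raw_j)
    return {
        "config": cfg, "panel": panel, "raw_i": raw_i, "raw_j": raw_j,
        "truth": truth, "study_i": study_i, "study_j": study_j,
    }


@pytest.fixture(scope="session")
def harmonized(sim_bundle):
    """Gene match table, shared genes and proxy-overlap calls for the pair."""
    table = eo.match_probes_to_genes(
        sim_bundle["raw_i"].probes, sim_bundle["raw_j"].probes,
        sim_bundle["raw_i"].annotation)
    shared = eo.shared_eqtl_genes(
        sim_bundle["study_i"], sim_bundle["study_j"], table)
    esnps = sorted(
        set(sim_bundle["study_i"].best_esnp().reindex(sorted(shared)).dropna())
        | set(sim_bundle["study_j"].best_esnp().reindex(sorted(shared)).dropna()))
    pm = eo.build_proxy_map(sim_bundle["panel"], esnps, 0.8, 100_000)
    calls = eo.proxy_overlap(
        sim_bundle["study_i"], sim_bundle["study_j"], shared, pm, pm)
    return {"table": table, "shared": shared, "proxy_map": pm, "calls": calls}


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
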