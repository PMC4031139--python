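"""Shared fixtures: small synthetic studies reused across test modules.

The expensive simulations are session-scoped; each is a deterministic
function of its hard-coded seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucbarrier.nucleosomes import call_nucleosomes, dyad_track, smooth_fft
from nucbarrier.simulate import BarrierClassSpec, SimulationConfig, simulate


def match_fraction(query: np.ndarray, reference: np.ndarray, tol: int = 10) -> float:
    """Fraction of query positions within ``tol`` bp of some reference position."""
    if len(query) == 0:
        return 0.0
    ref = np.sort(np.asarray(reference))
    q = np.asarray(query)
    i = np.searchsorted(ref, q)
    lo = np.abs(q - ref[np.clip(i - 1, 0, ref.size - 1)])
    hi = np.abs(q - ref[np.clip(i, 0, ref.size - 1)])
    return float((np.minimum(lo, hi) <= tol).mean())


def linker_study_config(seed: int = 1) -> SimulationConfig:
    """Two barrier classes with fixed 150-bp elements: long intergenic
    linkers (35 bp) vs short genic linkers (8 bp), sigma0 = 3, depth 50."""
    return SimulationConfig(
        chrom_sizes={"chr1": 1_600_000},
        n_genes=40,
        seed=seed,
        classes={
            "genic": BarrierClassSpec(40, 150, 150, linker=8, sigma0=3.0, dsigma=0.0),
            "intergenic": BarrierClassSpec(40, 150, 150, linker=35, sigma0=3.0, dsigma=0.0),
        },
    )


def recovery_study_config(seed: int = 2) -> SimulationConfig:
    """Zero-jitter arrays at digestion sigma 10 and depth 50, for
    dyad-recovery scoring against the ground truth."""
    cfg = SimulationConfig(seed=seed)
    for spec in cfg.classes.values():
        spec.sigma0 = 0.0
        spec.dsigma = 0.0
    cfg.minus1_occupancy = 0.0
    return cfg


def dense_background_config(seed: int = 3) -> SimulationConfig:
    """A genome dominated by unphased nucleosomes (5 dyads/kb) with only a
    handful of barrier arrays, for random-anchor flatness checks."""
    return SimulationConfig(
        chrom_sizes={"chr1": 2_000_000},
        n_genes=6,
        seed=seed,
        background_dyads_per_kb=5.0,
        depth=20,
        classes={"intergenic": BarrierClassSpec(5, 150, 150, linker=35)},
    )


@pytest.fixture(scope="session")
def linker_sim():
    return simulate(linker_study_config())


@pytest.fixture(scope="session")
def linker_calls(linker_sim):
    track, _ = dyad_track(linker_sim.fragments, linker_sim.sizes)
    return call_nucleosomes(smooth_fft(track))


@pytest.fixture(scope="session")
def recovery_sim():
    return simulate(recovery_study_config())


@pytest.fixture(scope="session")
def dense_background_sim():
    return simulate(dense_background_config())


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimulationConfig(seed=1))
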