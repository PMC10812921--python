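"""Shared fixtures: one study-scale simulation serves every directional test."""

from __future__ import annotations

import pytest

import bandselex as bx


@pytest.fixture(scope="session")
def directional_sim():
    """Four-round selection at library 50,000: POU1 monomer band vs
    POU1+BOB1 ternary band, one shared seed for the whole suite."""
    cfg = bx.SimulationConfig(
        library_size=50_000,
        rounds=4,
        conditions=(bx.Condition("POU1", bob1=False), bx.Condition("POU1", bob1=True)),
        seed=1,
    )
    return bx.run_selex(cfg)


@pytest.fixture(scope="session")
def directional_tables(directional_sim):
    """Final-round censuses for both arms."""
    return {
        label: bx.census(cres.final)
        for label, cres in directional_sim.per_condition.items()
    }


@pytest.fixture(scope="session")
def recovery_sim():
    """Monomer-band-only run at library 20,000, 4 rounds, seed 1."""
    cfg = bx.SimulationConfig(
        library_size=20_000,
        rounds=4,
        conditions=(bx.Condition("POU1", bob1=False),),
        seed=1,
    )
    return bx.run_selex(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Cheap two-round run for plumbing tests."""
    cfg = bx.SimulationConfig(
        library_size=3_000,
        rounds=2,
        conditions=(bx.Condition("POU1", bob1=True),),
        seed=7,
    )
    return bx.run_selex(cfg)
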