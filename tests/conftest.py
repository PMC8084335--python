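"""Shared fixtures.

Full 305-trial condition runs are expensive (the V-shaped arm integrates
at 2 ms), so they are computed once per session and shared by the
behavioural-signature tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from reachadapt.ofc import run_condition_ofc
from reachadapt.vsmodel import run_condition_vs


@pytest.fixture(scope="session")
def ofc_runs():
    """Per-trial tables for the optimal-control model, both variants."""
    out = {}
    for variant in ("flat", "hierarchical"):
        for cond in ("VDCF", "LIPF_NULL", "LIPF_PEC"):
            out[(variant, cond)] = run_condition_ofc(variant, cond)
    return out


@pytest.fixture(scope="session")
def vs_runs():
    """Per-trial tables for the V-shaped model, both variants."""
    out = {}
    for variant in ("flat", "hierarchical"):
        for cond in ("VDCF", "LIPF_NULL", "LIPF_PEC"):
            out[(variant, cond)] = run_condition_vs(variant, cond)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20210419)
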