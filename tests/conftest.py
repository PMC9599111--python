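"""Shared fixtures: small, fast synthetic datasets.

Unit tests run on a shortened paradigm (6 s trials, 128 Hz, few trials
per group) so the whole suite stays quick; the acceptance tests use the
full 19 s / 1200 Hz study paradigm where the check requires it.
"""

from __future__ import annotations

import numpy as np
import pytest

from oscinet import (
    Coupling,
    GroundTruth,
    ParadigmSpec,
    default_atlas,
    generate_dataset,
)

GROUPS = ("CG", "M-AIG", "F-AIG")


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_paradigm():
    """6 s trials at 128 Hz, 8/6/6 trials: fast but structurally complete."""
    return ParadigmSpec(
        baseline_window=(-2.0, -1.0),
        cue_window=(-1.0, 0.0),
        task_window=(0.0, 3.0),
        rest_lead=1.0,
        sampling_rate=128.0,
        group_sizes={"CG": 8, "M-AIG": 6, "F-AIG": 6},
    )


@pytest.fixture(scope="session")
def null_dataset(small_paradigm, atlas):
    """No planted effects: unit gains, no coupling, moderate noise."""
    return generate_dataset(small_paradigm, atlas, GroundTruth(noise_level=0.3), seed=11)


@pytest.fixture(scope="session")
def planted_dataset(small_paradigm, atlas):
    """One strong ERS ROI (alpha g=2 -> true ERSP 3) and one coupled pair."""
    truth = GroundTruth(
        ersp_gain={("cuneus_L", "alpha", g): 2.0 for g in GROUPS},
        coupling=tuple(
            Coupling("insula_L", "insula_R", "alpha", g, 5.0) for g in GROUPS
        ),
        noise_level=0.2,
    )
    return generate_dataset(small_paradigm, atlas, truth, seed=7)
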