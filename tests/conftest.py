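import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from enzymespace import synth
from enzymespace.synth import Segment


@pytest.fixture(scope="session")
def study():
    """The packaged synthetic study set (families, model, scores)."""
    return synth.make_study_set(seed=11)


@pytest.fixture(scope="session")
def helix_tail_model():
    """12-residue disordered (high-score) N-tail followed by a confident helix."""
    return synth.make_structure(
        [Segment("coil", 12, 0.8), Segment("helix", 30, 0.1)], seed=2
    )


@pytest.fixture(scope="session")
def helix_model():
    return synth.make_structure([Segment("helix", 20, 0.1)], seed=1)


@pytest.fixture(scope="session")
def pocket_fixtures():
    """All three pocket depth modes with their ligands and sites."""
    return {mode: synth.make_pocket_model(mode, seed=1) for mode in ("enclosed", "cleft", "flat")}
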