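import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from thiamodel import synth
from thiamodel.model import KineticLaw, Metabolite, PathwayModel, Reaction


@pytest.fixture(scope="session")
def thiamin_toy():
    return synth.make_thiamin_toy()


@pytest.fixture(scope="session")
def rice_network():
    return synth.make_rice_network()


@pytest.fixture(scope="session")
def rice_gapfilled():
    return synth.gapfill_rice_network()


@pytest.fixture()
def closed_mm1_model():
    """Closed S -> P single MM1 step: total mass is conserved."""
    return PathwayModel(
        [
            Metabolite("S", initial_concentration=10.0),
            Metabolite("P", initial_concentration=0.0),
        ],
        [
            Reaction(
                "conv",
                "E",
                {"S": -1.0, "P": 1.0},
                KineticLaw("MM1", ("S",), vmax=10.0, km=5.0),
            )
        ],
    )


@pytest.fixture()
def influx_fixture():
    """Constant influx 2 into S, MM1 consumption (Vmax=10, Km=5): S* = 1.25."""
    return synth.make_influx_mm1_fixture(k=2.0, vmax=10.0, km=5.0)
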