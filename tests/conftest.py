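import numpy as np
import pandas as pd
import pytest

from aopfinger.io import AOP, DEGTable, KEGeneSet, KeyEvent
from aopfinger.simulate import FixtureConfig


@pytest.fixture(scope="session")
def fixture_cfg() -> FixtureConfig:
    return FixtureConfig(seed=0)


@pytest.fixture
def two_aops() -> tuple[list[AOP], list[KeyEvent]]:
    kes = [
        KeyEvent("Ke01", "oxidative stress", "increase in reactive oxygen species", "MIE"),
        KeyEvent("Ke02", "inflammation", "secretion of proinflammatory mediators", "KE"),
        KeyEvent("Ke03", "fibrosis", "accumulation of collagen in the lung", "AO"),
        KeyEvent("Ke04", "cytotoxicity", "cell injury and death", "MIE"),
    ]
    aops = [
        AOP("Aop1", "stress to fibrosis", ("Ke01", "Ke02", "Ke03"),
            (("Ke01", "Ke02"), ("Ke02", "Ke03"))),
        AOP("Aop2", "injury to fibrosis", ("Ke04", "Ke02", "Ke03"),
            (("Ke04", "Ke02"), ("Ke02", "Ke03"))),
    ]
    return aops, kes


@pytest.fixture
def deg_table() -> DEGTable:
    frame = pd.DataFrame(
        {
            "gene": ["A", "B", "C", "D", "E"],
            "log2fc": [1.0, 0.5, -2.0, 2.0, np.nan],
            "adj_p": [0.01, 0.01, 0.001, 0.05, 0.01],
        }
    )
    return DEGTable("cmp1", frame)


@pytest.fixture
def ke_sets() -> list[KEGeneSet]:
    return [
        KEGeneSet("Ke01", frozenset({"A", "B", "C"})),
        KEGeneSet("Ke02", frozenset({"B", "C", "D"})),
        KEGeneSet("Ke03", frozenset({"A", "B", "C"})),
        KEGeneSet("Ke04", frozenset({"E"})),
    ]
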