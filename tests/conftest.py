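import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fopa
from fopa import (
    AnalysisConfig,
    EngineConfig,
    PathwayCollection,
    SimulationSpec,
    simulate_collection,
    simulate_expression,
)
from fopa.stats import GeneStatTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


KGML_MIN = """<?xml version="1.0"?>
<pathway name="path:test01" org="hsa" number="01">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""

KGML_RICH = """<?xml version="1.0"?>
<pathway name="path:test02" org="hsa" number="02">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20 hsa:21" type="gene"/>
  <entry id="3" name="C00001" type="compound"/>
  <entry id="4" name="hsa:30" type="gene"/>
  <entry id="5" name="hsa:40" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="activation"/>
  </relation>
  <relation entry1="3" entry2="4" type="PPrel">
    <subtype name="inhibition"/>
  </relation>
  <relation entry1="1" entry2="5" type="PPrel">
    <subtype name="binding/association"/>
  </relation>
</pathway>
"""


@pytest.fixture
def kgml_min() -> str:
    return KGML_MIN


@pytest.fixture
def kgml_rich() -> str:
    return KGML_RICH


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    return SimulationSpec()


@pytest.fixture(scope="session")
def signal_study(default_spec):
    """One synthetic signal dataset at the default study conditions."""
    coll = simulate_collection(default_spec)
    data = simulate_expression(default_spec, coll)
    return default_spec, coll, data


@pytest.fixture(scope="session")
def mc_config() -> AnalysisConfig:
    return AnalysisConfig(
        n_perm=100, seed=11, engine=EngineConfig(engine="monte_carlo", n_traj=1000)
    )


def make_stat_table(
    genes: list[str],
    T: dict[str, float] | None = None,
    de: set[str] | None = None,
    P: dict[str, float] | None = None,
    v: float = 0.05,
) -> GeneStatTable:
    """Hand-built per-gene table for unit tests (bypasses the pipeline)."""
    T = T or {}
    de = de or set()
    P = P or {}
    q = [0.0 if g in de else 1.0 for g in genes]
    table = pd.DataFrame(
        {
            "T": [T.get(g, 0.0) for g in genes],
            "p": np.nan,
            "q": q,
            "is_de": [g in de for g in genes],
            "f": 1,
            "Fn": 1.0,
            "P": [P.get(g, 0.0) for g in genes],
        },
        index=genes,
    )
    return GeneStatTable(table=table, v=v)


def single_pathway_collection(g: fopa.PathwayGraph) -> PathwayCollection:
    return PathwayCollection([g])
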