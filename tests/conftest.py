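import numpy as np
import pytest

from lycoscreen.gsmn import MetabolicModel, Metabolite, Reaction
from lycoscreen.pb_design import read_design
from lycoscreen.pipeline import packaged_design
from lycoscreen.synthetic_data import ToyModelSpec, make_toy_model, toy_candidates


def model_from_arrays(s, lb, ub, growth_idx=0, target_idx=0) -> MetabolicModel:
    """Wrap a raw (S, lb, ub) system in a MetabolicModel for fba()."""
    n_mets, n_rxns = s.shape
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {f"m{i}": float(s[i, j]) for i in range(n_mets) if s[i, j] != 0}
        rxns.append(Reaction(f"r{j}", stoich, lower_bound=float(lb[j]),
                             upper_bound=float(ub[j])))
    return MetabolicModel(mets, rxns, f"r{growth_idx}", f"r{target_idx}")


@pytest.fixture(scope="session")
def table1():
    design, warnings = read_design(*packaged_design("fba_independent"))
    assert warnings == []
    return design


@pytest.fixture(scope="session")
def table4():
    design, warnings = read_design(*packaged_design("fba_predicted"))
    assert warnings == []
    return design


@pytest.fixture()
def toy_spec():
    return ToyModelSpec()


@pytest.fixture()
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


@pytest.fixture()
def toy_cands(toy_spec):
    return toy_candidates(toy_spec)


@pytest.fixture()
def chain_model():
    """Single-path chain: uptake capacity 10 flows A -> sink one-to-one."""
    mets = [Metabolite("a")]
    rxns = [
        Reaction("EX_a", {"a": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        Reaction("SINK", {"a": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(mets, rxns, "SINK", "SINK")
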