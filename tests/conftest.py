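import logging

import pytest

from metpath import (
    ConditionSpec,
    ModelNetwork,
    Metabolite,
    Reaction,
    ToySpec,
    estimate_flux_state,
    flag_cofactors,
    make_toy_model,
)

logging.getLogger("metpath").setLevel(logging.ERROR)

#: objective reaction used to drive flux through each toy topology
TOY_OBJECTIVES = {
    "chain": "R2",
    "diamond": "EX_B",
    "branch": "EX_C",
    "cycle": "EX_B",
    "cofactor_trap": "EX_B",
}


def toy_with_state(topology: str, cofactors=("atp", "adp")):
    """Build a toy model, flag cofactors, and solve its flux state."""
    model, efms = make_toy_model(ToySpec(topology))
    model = flag_cofactors(model, set(cofactors))
    cond = ConditionSpec(
        name=f"toy_{topology}", objective_reaction=TOY_OBJECTIVES[topology]
    )
    state = estimate_flux_state(model, cond)
    return model, state, efms


@pytest.fixture(scope="session")
def chain():
    return toy_with_state("chain")


@pytest.fixture(scope="session")
def diamond():
    return toy_with_state("diamond")


@pytest.fixture(scope="session")
def branch():
    return toy_with_state("branch")


@pytest.fixture(scope="session")
def cycle():
    return toy_with_state("cycle")


@pytest.fixture(scope="session")
def cofactor_trap():
    return toy_with_state("cofactor_trap")


def simple_model(reactions, metabolite_ids):
    mets = [Metabolite(mid, compartment="c") for mid in metabolite_ids]
    return ModelNetwork(id="custom", metabolites=mets, reactions=reactions)


@pytest.fixture
def expression_file(tmp_path):
    def write(rows, name="expr.tsv", header="gene\tfold_change"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return write
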