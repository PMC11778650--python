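import numpy as np
import pytest

from sulfurflux.core import MetabolicModel, Metabolite, Reaction
from sulfurflux.synth import ToyModelConfig, build_desulfurization_toy


@pytest.fixture(scope="session")
def toy():
    """The default synthetic desulfurization model (treat as read-only;
    copy before mutating)."""
    return build_desulfurization_toy()


@pytest.fixture(scope="session")
def toy_dbt(toy):
    """Toy conditioned on DBT as the sole sulfur source, glucose carbon."""
    m = toy.copy()
    m.set_bounds("EX_so4", 0, 1000)
    m.set_bounds("EX_h2s", 0, 1000)
    m.set_bounds("EX_dbt", -10, 0)
    return m


def chain_model(uptake=(-1.0, 1000.0), expand=1.0):
    """Linear chain EX_A -> A -> (expand) B -> biomass(B); the standard
    textbook FBA example whose optimum and duals are known in closed form."""
    mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[c]": -1.0},
                 lower_bound=uptake[0], upper_bound=uptake[1],
                 kind="exchange"),
        Reaction(id="R1", stoichiometry={"A[c]": -1.0, "B[c]": expand},
                 lower_bound=0, upper_bound=1000),
        Reaction(id="BIO", stoichiometry={"B[c]": -1.0},
                 lower_bound=0, upper_bound=1000, kind="biomass"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                          objective="BIO",
                          compartments={"c": "cytosol"}).validate()


def random_small_model(rng, n_mets=None, n_rxns=None):
    """Random bounded stoichiometric LP: m x n sparse integer S, finite
    bounds containing zero (so v = 0 is always feasible), one random
    reaction nominated as objective."""
    m = int(n_mets if n_mets is not None else rng.integers(2, 7))
    n = int(n_rxns if n_rxns is not None else rng.integers(m + 1, 9))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        mask = rng.random((m, n)) < 0.4
        S[mask] = 0.0
        if np.all(np.abs(S).sum(axis=0) > 0) and np.all(np.abs(S).sum(axis=1) > 0):
            break
    mets = [Metabolite(id=f"m{i}[c]") for i in range(m)]
    rxns = []
    for j in range(n):
        lb = float(rng.choice([-2.0, -1.0, 0.0]))
        ub = float(rng.choice([1.0, 2.0]))
        stoich = {f"m{i}[c]": S[i, j] for i in range(m) if S[i, j] != 0}
        rxns.append(Reaction(id=f"r{j}", stoichiometry=stoich,
                             lower_bound=lb, upper_bound=ub))
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                           compartments={"c": "c"})
    objective = f"r{int(rng.integers(0, n))}"
    return model, objective
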