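import numpy as np
import pytest

from metclust.model_io import (
    ExpressionMatrix,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from metclust.synthetic_data import SyntheticSpec, generate_dataset


def make_model(reactions, compartment="c"):
    """Build a MetabolicModel from (rid, substrates, products, genes) tuples
    using bare metabolite names in one compartment."""
    mets: dict[str, Metabolite] = {}
    rxns = []
    for rid, subs, prods, genes in reactions:
        qs, qp = [], []
        for name, dest in ((subs, qs), (prods, qp)):
            for m in name:
                met = Metabolite(raw_id=m, name=m, compartment=compartment)
                mets.setdefault(met.node_id, met)
                dest.append(met.node_id)
        rxns.append(
            Reaction(id=rid, substrates=tuple(qs), products=tuple(qp), genes=frozenset(genes))
        )
    return MetabolicModel(metabolites=mets, reactions=rxns, source="test")


@pytest.fixture
def fig_model():
    """The two-reaction worked example: R1 (genes G1, G2) converts M1, M2 to
    M4; R2 (gene G3) converts M1 to M4."""
    return make_model(
        [
            ("R1", ["M1", "M2"], ["M4"], ["G1", "G2"]),
            ("R2", ["M1"], ["M4"], ["G3"]),
        ]
    )


@pytest.fixture
def fig_expression():
    return ExpressionMatrix(
        genes=["G1", "G2", "G3"],
        samples=["P1"],
        values=np.array([[0.25], [0.15], [0.10]]),
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Scaled-down two-class cohort shared by integration tests."""
    spec = SyntheticSpec(
        n_metabolites=80,
        n_reactions=130,
        n_samples_per_class=8,
        n_classes=2,
        seed=11,
    )
    model, expr, labels = generate_dataset(spec)
    return spec, model, expr, labels


def random_symmetric_weights(rng, k, density=0.6):
    """Random symmetric non-negative weight matrix with zero or retained
    diagonal, as produced by supernode collapse."""
    W = rng.random((k, k)) * (rng.random((k, k)) < density)
    W = np.triu(W)
    return W + np.triu(W, 1).T
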