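"""Synthetic metabolic models and class-structured expression matrices.

The generator emulates the statistical structure the clustering method
assumes: every sample shares one metabolic topology, and patient classes
differ only in the distribution of edge weights, which are driven by gene
expression. Expression is lognormal (positive and right-skewed, like
FPKM), and each class multiplies a class-specific gene subset by a
constant effect, so the class signal propagates to the networks through
the same construction rules as real data.

The model generator produces a connected metabolite graph (a spanning
backbone of sequential conversions plus random extra reactions), a
configurable fraction of uncatalyzed reactions (exercising the drop rule)
and a configurable number of currency metabolites attached to many
reactions (exercising the exclusion filter). Everything is deterministic
given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_io import (
    ExpressionMatrix,
    MetabolicModel,
    Metabolite,
    Reaction,
    default_exclusion_list,
)

__all__ = ["SyntheticSpec", "generate_model", "generate_expression", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-level generator.

    Defaults describe a toy cohort: a shared ~500-metabolite topology and
    two classes of 30 samples whose class-specific genes are upregulated
    10-fold over lognormal(0, 0.2) baseline expression.
    """

    n_metabolites: int = 500
    n_reactions: int = 800
    genes_per_reaction: tuple[int, int] = (1, 3)
    n_compartments: int = 1
    n_samples_per_class: int = 30
    n_classes: int = 2
    class_effect: float = 10.0
    noise_sd: float = 0.2
    seed: int = 0
    fraction_uncatalyzed: float = 0.05
    n_currency: int = 3
    currency_attach_fraction: float = 0.2
    class_gene_fraction: float = 0.2
    n_genes: int | None = None  # default: one gene symbol pool entry per reaction

    def __post_init__(self) -> None:
        if min(
            self.n_metabolites,
            self.n_reactions,
            self.n_compartments,
            self.n_samples_per_class,
            self.n_classes,
        ) < 1:
            raise ValueError("all counts must be positive")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be positive")
        if self.n_currency >= self.n_metabolites:
            raise ValueError("more currency metabolites than metabolites")

    @property
    def gene_pool_size(self) -> int:
        return self.n_genes if self.n_genes is not None else self.n_reactions


_CURRENCY_NAMES = sorted(default_exclusion_list())


def generate_model(spec: SyntheticSpec) -> MetabolicModel:
    """Random connected reaction network with currency metabolites and a
    fraction of uncatalyzed reactions; deterministic given ``spec.seed``."""
    rng = np.random.default_rng([spec.seed, 101])
    comps = [chr(ord("c") + i) for i in range(spec.n_compartments)]
    mets: dict[str, Metabolite] = {}
    ordinary: list[str] = []
    for comp in comps:
        for i in range(spec.n_metabolites):
            m = Metabolite(raw_id=f"M{i:04d}", name=f"M{i:04d}", compartment=comp)
            mets[m.node_id] = m
            ordinary.append(m.node_id)
    currency: list[str] = []
    for name in _CURRENCY_NAMES[: spec.n_currency]:
        m = Metabolite(raw_id=name, name=name, compartment=comps[0])
        mets[m.node_id] = m
        currency.append(m.node_id)

    genes = [f"G{i:05d}" for i in range(spec.gene_pool_size)]
    lo, hi = spec.genes_per_reaction
    reactions: list[Reaction] = []

    def sample_genes() -> frozenset[str]:
        size = int(rng.integers(lo, hi + 1))
        return frozenset(rng.choice(genes, size=size, replace=False))

    # spanning backbone over the ordinary metabolites keeps the graph connected
    n_backbone = len(ordinary) - 1
    if spec.n_reactions < n_backbone:
        n_backbone = spec.n_reactions
    for i in range(n_backbone):
        reactions.append(
            Reaction(
                id=f"R{i:05d}",
                substrates=(ordinary[i],),
                products=(ordinary[i + 1],),
                genes=sample_genes(),
                reversible=bool(rng.integers(0, 2)),
            )
        )
    for i in range(n_backbone, spec.n_reactions):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(len(ordinary), size=n_sub + n_prod, replace=False)
        reactions.append(
            Reaction(
                id=f"R{i:05d}",
                substrates=tuple(ordinary[p] for p in picks[:n_sub]),
                products=tuple(ordinary[p] for p in picks[n_sub:]),
                genes=sample_genes(),
                reversible=bool(rng.integers(0, 2)),
            )
        )

    # attach currency metabolites as extra substrates of many reactions
    for cur in currency:
        n_attach = int(round(spec.currency_attach_fraction * len(reactions)))
        for ridx in rng.choice(len(reactions), size=n_attach, replace=False):
            r = reactions[ridx]
            reactions[ridx] = Reaction(
                r.id, (*r.substrates, cur), r.products, r.genes, r.reversible
            )

    # strip gene associations from a random fraction (uncatalyzed reactions)
    n_uncat = int(round(spec.fraction_uncatalyzed * len(reactions)))
    for ridx in rng.choice(len(reactions), size=n_uncat, replace=False):
        r = reactions[ridx]
        reactions[ridx] = Reaction(
            r.id, r.substrates, r.products, frozenset(), r.reversible
        )

    return MetabolicModel(
        metabolites=mets, reactions=reactions, source=f"synthetic(seed={spec.seed})"
    )


def generate_expression(
    model: MetabolicModel, spec: SyntheticSpec
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Lognormal baseline expression with multiplicative per-class effects
    on disjoint class-specific gene subsets; returns the matrix and the
    ground-truth sample labels."""
    rng = np.random.default_rng([spec.seed, 202])
    genes = sorted(model.genes)
    n_genes = len(genes)
    n_samples = spec.n_classes * spec.n_samples_per_class
    samples = [f"S{j:03d}" for j in range(n_samples)]
    classes = [f"C{c + 1}" for c in range(spec.n_classes)]
    labels = {
        s: classes[j // spec.n_samples_per_class] for j, s in enumerate(samples)
    }

    values = rng.lognormal(mean=0.0, sigma=spec.noise_sd, size=(n_genes, n_samples))

    subset_size = int(spec.class_gene_fraction * n_genes)
    shuffled = rng.permutation(n_genes)
    for c in range(spec.n_classes):
        subset = shuffled[c * subset_size : (c + 1) * subset_size]
        cols = [j for j, s in enumerate(samples) if labels[s] == classes[c]]
        values[np.ix_(subset, cols)] *= spec.class_effect

    expr = ExpressionMatrix(genes=genes, samples=samples, values=values, labels=labels)
    return expr, labels


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[MetabolicModel, ExpressionMatrix, dict[str, str]]:
    """Generate model + expression + labels, optionally writing them through
    the public tabular/TSV writers (the synthetic path uses only public
    interfaces)."""
    model = generate_model(spec)
    expr, labels = generate_expression(model, spec)
    if out_dir is not None:
        from .model_io import write_expression, write_labels, write_model_tabular

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_model_tabular(model, out / "model.tsv")
        write_expression(expr, out / "expression.tsv")
        write_labels(labels, out / "labels.tsv")
    return model, expr, labels
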