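"""Reading and validation of metabolic models, expression matrices and
auxiliary files.

A metabolic model is a set of reactions over compartment-qualified
metabolites, each reaction annotated with the genes encoding its catalysts
(GPR associations). The same chemical species in two compartments is two
distinct metabolites: node identity is the pair ``(name, compartment)``.

Two model formats are accepted:

* an SBML subset (Level 2/3, fbc gene-product associations), read through
  cobrapy;
* a plain tabular dialect — TSV with columns ``reaction_id``,
  ``substrates``, ``products`` (``;``-separated compartment-qualified ids
  like ``M1[c]``), ``genes`` (``;``-separated symbols, empty allowed) and
  ``reversible`` (0/1).

Gene-association boolean expressions (AND/OR trees) are flattened to the
set of gene symbols appearing in them; the downstream edge-weight rule
(within-reaction average, between-reaction sum) is the only AND/OR
semantics applied. Stoichiometric coefficients are read but only the
substrate/product role is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ExpressionMatrix",
    "ModelValidationError",
    "read_model",
    "write_model_tabular",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_exclusion_list",
    "default_exclusion_list",
    "remove_recurrent_metabolites",
    "drop_uncatalyzed_reactions",
]


class ModelValidationError(ValueError):
    """Raised when a model file violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A compartment-qualified metabolite node."""

    raw_id: str
    name: str
    compartment: str

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.raw_id!r} has an empty compartment label"
            )

    @property
    def node_id(self) -> str:
        """Canonical node identifier, e.g. ``M1[c]``."""
        return f"{self.raw_id}[{self.compartment}]"


@dataclass(frozen=True)
class Reaction:
    """A reaction with substrate/product roles and its catalyzing genes.

    ``substrates`` and ``products`` are tuples of metabolite node ids.
    A reaction with an empty gene set is "uncatalyzed" and contributes no
    edges to any sample network.
    """

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    genes: frozenset[str]
    reversible: bool = False

    @property
    def uncatalyzed(self) -> bool:
        return len(self.genes) == 0


@dataclass
class MetabolicModel:
    """A collection of metabolites and reactions with GPR associations."""

    metabolites: dict[str, Metabolite]  # node_id -> Metabolite
    reactions: list[Reaction]
    source: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        for r in self.reactions:
            for m in (*r.substrates, *r.products):
                if m not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}"
                    )

    @property
    def genes(self) -> frozenset[str]:
        """Union of all gene symbols appearing in GPR associations."""
        out: set[str] = set()
        for r in self.reactions:
            out.update(r.genes)
        return frozenset(out)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self.metabolites)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized expression values
    (e.g. FPKM), optionally with ground-truth class labels per sample."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def value(self, gene: str, sample: str) -> float:
        return float(self.values[self._gene_index[gene], self._sample_index[sample]])

    def sample_column(self, sample: str) -> np.ndarray:
        if sample not in self._sample_index:
            raise KeyError(f"sample {sample!r} not in expression matrix")
        return self.values[:, self._sample_index[sample]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


# ---------------------------------------------------------------------------
# model readers / writers


def _parse_qualified_id(token: str, default_compartment: str = "c") -> Metabolite:
    token = token.strip()
    if token.endswith("]") and "[" in token:
        raw, comp = token[:-1].rsplit("[", 1)
    else:
        raw, comp = token, default_compartment
    if not raw:
        raise ModelValidationError(f"malformed metabolite id {token!r}")
    return Metabolite(raw_id=raw, name=raw, compartment=comp)


def _split_field(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [t.strip() for t in str(cell).split(";") if t.strip()]


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from an SBML or tabular file.

    Parameters
    ----------
    path:
        Model file. ``.xml``/``.sbml`` are treated as SBML unless
        ``format`` says otherwise.
    format:
        ``"sbml"`` or ``"tabular"``; inferred from the extension when None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tabular"
    if format == "sbml":
        return _read_sbml(path)
    if format == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    # cobrapy handles Level 2/3, notes-style and fbc gene associations; the
    # GPR boolean tree is flattened to the set of gene symbols.
    from cobra.io import read_sbml_model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmodel = read_sbml_model(str(path))
    metabolites: dict[str, Metabolite] = {}
    for m in cmodel.metabolites:
        met = Metabolite(
            raw_id=m.id,
            name=m.name or m.id,
            compartment=m.compartment or "c",
        )
        metabolites[met.node_id] = met
    by_raw = {m.raw_id: nid for nid, m in metabolites.items()}
    reactions: list[Reaction] = []
    for r in cmodel.reactions:
        subs = tuple(by_raw[m.id] for m, c in r.metabolites.items() if c < 0)
        prods = tuple(by_raw[m.id] for m, c in r.metabolites.items() if c > 0)
        genes = frozenset(g.id for g in r.genes)
        reactions.append(
            Reaction(
                id=r.id,
                substrates=subs,
                products=prods,
                genes=genes,
                reversible=r.reversibility,
            )
        )
    return MetabolicModel(metabolites=metabolites, reactions=reactions, source=str(path))


_TABULAR_COLUMNS = ["reaction_id", "substrates", "products", "genes", "reversible"]


def _read_tabular(path: Path) -> MetabolicModel:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - surfaced with filename
        raise ModelValidationError(f"cannot parse tabular model {path}: {exc}") from exc
    missing = [c for c in _TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise ModelValidationError(
            f"tabular model {path} lacks required columns {missing}"
        )
    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    for row in df.itertuples(index=False):
        subs, prods = [], []
        for cell, dest in ((row.substrates, subs), (row.products, prods)):
            for token in _split_field(cell):
                met = _parse_qualified_id(token)
                metabolites.setdefault(met.node_id, met)
                dest.append(met.node_id)
        reactions.append(
            Reaction(
                id=str(row.reaction_id),
                substrates=tuple(subs),
                products=tuple(prods),
                genes=frozenset(_split_field(row.genes)),
                reversible=str(row.reversible).strip() in {"1", "True", "true"},
            )
        )
    if not reactions:
        logger.warning("model %s contains no reactions", path)
    return MetabolicModel(metabolites=metabolites, reactions=reactions, source=str(path))


def write_model_tabular(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the tabular dialect (round-trips with read_model)."""
    rows = [
        {
            "reaction_id": r.id,
            "substrates": ";".join(r.substrates),
            "products": ";".join(r.products),
            "genes": ";".join(sorted(r.genes)),
            "reversible": int(r.reversible),
        }
        for r in model.reactions
    ]
    pd.DataFrame(rows, columns=_TABULAR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression / labels / exclusion lists


def read_expression(path: str | Path, labels: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression table (TSV or CSV by extension).

    First column holds gene symbols, the header row holds sample ids, and
    the body must be non-negative numeric.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = sorted({s for s in header if header.count(s) > 1})
    if dup_cols:
        raise ValueError(f"duplicate sample columns in {path}: {dup_cols}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene rows in {path}: {dup_genes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        bad = df.map(lambda x: not _is_number(x))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        ) from None
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression value in {path} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=values,
        labels=dict(labels) if labels else None,
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    expr.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> class TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample_id, class)")
    first = df.iloc[0]
    if str(first[0]).lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, c in labels.items():
            fh.write(f"{s}\t{c}\n")


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read a recurrent-metabolite list: one bare name per line, '#' comments."""
    names = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.add(line)
    return frozenset(names)


def default_exclusion_list() -> frozenset[str]:
    """Built-in currency-metabolite list (H2O, CO2, ATP, NADH, ...).

    A replaceable stand-in for a model-specific list; override via
    :func:`read_exclusion_list` on your own file.
    """
    text = resources.files("metclust.data").joinpath("currency_metabolites.txt").read_text()
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    )


# ---------------------------------------------------------------------------
# model-level filters


def remove_recurrent_metabolites(
    model: MetabolicModel, exclusion_list: Iterable[str]
) -> MetabolicModel:
    """Delete currency metabolites (matched by case-insensitive bare name in
    every compartment) and prune reactions left without substrates or
    products. Idempotent; unknown names are ignored with a logged count."""
    excl = {str(n).lower() for n in exclusion_list}

    def hit(met: Metabolite) -> bool:
        return met.name.lower() in excl or met.raw_id.lower() in excl

    kept = {nid: m for nid, m in model.metabolites.items() if not hit(m)}
    removed = len(model.metabolites) - len(kept)
    matched_names = {
        m.name.lower() if m.name.lower() in excl else m.raw_id.lower()
        for m in model.metabolites.values()
        if hit(m)
    }
    unmatched = len(excl - matched_names)
    if unmatched:
        logger.info("%d exclusion-list entries matched no metabolite", unmatched)
    logger.info("removed %d recurrent metabolites", removed)

    reactions: list[Reaction] = []
    dropped = 0
    for r in model.reactions:
        subs = tuple(m for m in r.substrates if m in kept)
        prods = tuple(m for m in r.products if m in kept)
        if (r.substrates and not subs) or (r.products and not prods):
            dropped += 1
            continue
        reactions.append(
            Reaction(r.id, subs, prods, r.genes, r.reversible)
            if (subs != r.substrates or prods != r.products)
            else r
        )
    if dropped:
        logger.info("dropped %d reactions emptied by recurrent-metabolite removal", dropped)
    return MetabolicModel(metabolites=kept, reactions=reactions, source=model.source)


def drop_uncatalyzed_reactions(model: MetabolicModel) -> MetabolicModel:
    """Drop reactions with no gene association (they carry no expression
    weight and would contribute sample-independent structure only)."""
    reactions = [r for r in model.reactions if not r.uncatalyzed]
    n = len(model.reactions) - len(reactions)
    if n:
        logger.info("dropped %d uncatalyzed reactions", n)
    return MetabolicModel(
        metabolites=dict(model.metabolites), reactions=reactions, source=model.source
    )
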