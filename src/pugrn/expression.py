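"""Expression matrices, standardization, and gene-pair feature vectors.

A candidate regulation (A, B) is represented to the classifier as the
concatenation ``(e(A); e(B))`` of the two genes' expression profiles
across all conditions, each profile standardized to zero mean and unit
standard deviation.  For a simulated dataset with G genes there are
G + 1 conditions (wild-type plus one knockdown per gene), so the pair
feature vector has 2 × (G + 1) attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Edge, LabelPartition, all_ordered_pairs

__all__ = [
    "ExpressionMatrix",
    "PairExample",
    "standardize_profiles",
    "pair_features",
    "build_pair_dataset",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × conditions matrix of expression levels.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` under
    ``condition_ids[j]``.  Raw (pre-standardization) values must be
    finite; simulated data are additionally nonnegative and globally
    normalized so the dataset maximum is one.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(self.gene_ids)} genes "
                f"× {len(self.condition_ids)} conditions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]


@dataclass(frozen=True)
class PairExample:
    """One ordered gene pair with its feature vector and labels.

    ``y`` is the true class (1 = the regulation exists), ``s`` the
    observed label (1 = known positive).  ``s = 1`` implies ``y = 1``:
    only true regulations are ever labeled.
    """

    regulator: str
    target: str
    x: np.ndarray = field(repr=False)
    y: int
    s: int

    def __post_init__(self) -> None:
        if self.s == 1 and self.y != 1:
            raise ValueError("a labeled example (s=1) must be positive (y=1)")

    @property
    def pair(self) -> Edge:
        return (self.regulator, self.target)


def standardize_profiles(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene's profile to zero mean, unit (population) sd.

    Zero-variance rows map to all-zeros rather than raising — constant
    rows occur legitimately in noiseless knockout simulations.
    """
    if expr.n_conditions < 2:
        raise ValueError("standardization needs at least two conditions")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, keepdims=True)  # population sd, ddof=0
    centered = expr.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        standardized = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(expr.gene_ids, expr.condition_ids, standardized)


def pair_features(expr_std: ExpressionMatrix, regulator: str, target: str) -> np.ndarray:
    """Feature vector for the hypothesis "regulator regulates target".

    The concatenation of the two (standardized) profiles, length
    ``2 × n_conditions``.  Order matters: (A, B) and (B, A) give
    different vectors whenever the profiles differ.
    """
    if regulator == target:
        raise ValueError("self-pairs are not valid examples")
    return np.concatenate([expr_std.row(regulator), expr_std.row(target)])


def build_pair_dataset(expr: ExpressionMatrix, partition: LabelPartition) -> list[PairExample]:
    """Assemble one PairExample per ordered non-self pair, in lexicographic order.

    Profiles are standardized before concatenation.  Labels follow the
    partition: P pairs get ``(y=1, s=1)``, Q pairs ``(y=1, s=0)``, N
    pairs ``(y=0, s=0)``.
    """
    if set(partition.genes) - set(expr.gene_ids):
        missing = sorted(set(partition.genes) - set(expr.gene_ids))
        raise ValueError(f"partition genes missing from expression matrix: {missing}")
    std = standardize_profiles(expr)
    row_index = {g: std.gene_index(g) for g in partition.genes}
    examples: list[PairExample] = []
    for a, b in all_ordered_pairs(partition.genes):
        pair = (a, b)
        if pair in partition.P:
            y, s = 1, 1
        elif pair in partition.Q:
            y, s = 1, 0
        else:
            y, s = 0, 0
        x = np.concatenate([std.values[row_index[a]], std.values[row_index[b]]])
        examples.append(PairExample(a, b, x, y, s))
    return examples
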