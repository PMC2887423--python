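"""Small synthetic datasets with known ground truth, for tests and demos.

These generators produce the controlled inputs the test suite relies
on: a three-gene regulatory chain with noiseless knockout expression, a
two-Gaussian positive-unlabeled sample whose true posterior is
available in closed form (so probability calibration can be scored
exactly), and a per-transcription-factor regulon fixture with signal
planted in the regulated genes' profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .expression import ExpressionMatrix, PairExample
from .network import GeneNetwork
from .simulate import SimulationConfig, simulate_expression

__all__ = [
    "chain_network",
    "chain_fixture",
    "GaussianPUSample",
    "gaussian_pu_sample",
    "gaussian_pu_examples",
    "regulon_fixture",
]

#: Mean separation of the two Gaussian classes, in units of their (unit) sd.
GAUSSIAN_SEPARATION = 4.0
#: Prior probability of the positive class in the Gaussian PU sample.
GAUSSIAN_PRIOR = 0.5


def gaussian_svm_config():
    """SVM hyperparameters for the 2-D Gaussian fixture (C=1, γ=0.5)."""
    from .pu import SvmConfig

    return SvmConfig(C=1.0, gamma=0.5)


def chain_network() -> GeneNetwork:
    """The canonical 3-gene chain a → b → c."""
    return GeneNetwork.from_edges({("a", "b"), ("b", "c")}, genes=("a", "b", "c"))


def chain_fixture(seed: int = 0) -> tuple[GeneNetwork, ExpressionMatrix]:
    """The chain network with noiseless, all-activating knockout expression."""
    net = chain_network()
    config = SimulationConfig(n_genes=3, noise_sd=0.0, activation_prob=1.0, seed=seed)
    return net, simulate_expression(net, config)


@dataclass(frozen=True)
class GaussianPUSample:
    """A positive-unlabeled draw from two known Gaussians.

    ``X`` are features, ``y`` true classes, ``s`` observed labels
    (each positive labeled independently with probability ``c_true``),
    and ``posterior`` the exact p(y=1|x) for every row — computable here
    because both class densities are known.
    """

    X: np.ndarray
    y: np.ndarray
    s: np.ndarray
    posterior: np.ndarray
    c_true: float

    def true_posterior(self, X: np.ndarray) -> np.ndarray:
        return _gaussian_posterior(np.asarray(X, dtype=float))


def _gaussian_posterior(X: np.ndarray) -> np.ndarray:
    dim = X.shape[1]
    offset = GAUSSIAN_SEPARATION / 2.0
    mu_pos = np.zeros(dim)
    mu_pos[0] = offset
    mu_neg = np.zeros(dim)
    mu_neg[0] = -offset
    d_pos = multivariate_normal(mean=mu_pos).pdf(X)
    d_neg = multivariate_normal(mean=mu_neg).pdf(X)
    return GAUSSIAN_PRIOR * d_pos / (GAUSSIAN_PRIOR * d_pos + (1 - GAUSSIAN_PRIOR) * d_neg)


def gaussian_pu_sample(
    n: int = 2000, c_true: float = 0.5, seed: int = 0, dim: int = 2
) -> GaussianPUSample:
    """Draw a PU sample from two unit-covariance Gaussians.

    Classes are balanced; class means sit ``GAUSSIAN_SEPARATION``
    standard deviations apart along the first axis.  Each true positive
    is labeled with probability ``c_true`` (selected completely at
    random), matching the assumption under which the PosOnly correction
    is exact.
    """
    if not 0 < c_true <= 1:
        raise ValueError("c_true must be in (0, 1]")
    rng = np.random.default_rng(int(seed) % 2**31)
    y = (rng.random(n) < GAUSSIAN_PRIOR).astype(int)
    offset = GAUSSIAN_SEPARATION / 2.0
    X = rng.normal(size=(n, dim))
    X[:, 0] += np.where(y == 1, offset, -offset)
    s = np.where((y == 1) & (rng.random(n) < c_true), 1, 0)
    return GaussianPUSample(X=X, y=y, s=s, posterior=_gaussian_posterior(X), c_true=c_true)


def gaussian_pu_examples(sample: GaussianPUSample) -> list[PairExample]:
    """Wrap a Gaussian PU sample as PairExamples for the classifier API."""
    return [
        PairExample(f"p{i}", f"q{i}", sample.X[i], int(sample.y[i]), int(sample.s[i]))
        for i in range(len(sample.y))
    ]


def regulon_fixture(
    n_genes: int = 30,
    n_regulated: int = 9,
    n_conditions: int = 40,
    signal_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """One TF regulating a block of genes with correlated profiles.

    The regulated genes share a common condition-response template (plus
    gene-specific noise of scale ``signal_sd``); unregulated genes are
    independent noise.  Expression is exponentiated so raw values stay
    positive, mimicking intensity data.  Returns the matrix and a
    ``{TF: regulated genes}`` mapping; the TF itself is the first gene.
    """
    if n_regulated >= n_genes:
        raise ValueError("n_regulated must be smaller than n_genes")
    rng = np.random.default_rng(int(seed) % 2**31)
    genes = ["tf0"] + [f"t{i:02d}" for i in range(1, n_genes)]
    template = rng.normal(size=n_conditions)
    values = np.empty((n_genes, n_conditions))
    values[0] = template + rng.normal(scale=signal_sd, size=n_conditions)
    regulated = set(genes[1 : 1 + n_regulated])
    for i in range(1, n_genes):
        if genes[i] in regulated:
            values[i] = template + rng.normal(scale=signal_sd, size=n_conditions)
        else:
            values[i] = rng.normal(size=n_conditions)
    expr = ExpressionMatrix(tuple(genes), tuple(f"cond{j:02d}" for j in range(n_conditions)),
                            np.exp(values))
    return expr, {"tf0": regulated}
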