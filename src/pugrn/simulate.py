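"""Desk-scale simulator of regulatory networks and knockout expression data.

Emulates the kind of steady-state benchmark data produced by in-silico
network generators such as GeneNetWeaver: a random, predominantly
tree-like directed network of G genes, plus a G × (G + 1) expression
matrix holding the wild-type steady state and one steady state per
single-gene knockdown, with multiplicative measurement noise, globally
normalized so the dataset maximum is one.

The kinetic model is deliberately simple.  Each gene g has a basal
synthesis rate b_g modulated multiplicatively by its regulators through
Hill-type activation or repression terms; each edge carries a sampled
regulation *strength* β ∈ (0, 1), the fraction of synthesis under the
regulator's control, so a fully silenced activator reduces its target
to the (1 − β) basal remainder rather than to zero.  Degradation is
first-order with unit rate, so the steady state solves x = F(x), found
by damped fixed-point iteration.  A knockdown scales the whole
synthesis term of the targeted gene by a residual factor (0 for a null
mutant); because targets retain basal output, the perturbation
*attenuates* as it propagates, so direct targets respond more strongly
than indirect descendants — the contrast a pair classifier learns
regulation from, and the reason transitive (indirect) pairs are
distinguishable from true edges at all in steady-state data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .expression import ExpressionMatrix
from .network import GeneNetwork

__all__ = ["SimulationConfig", "generate_network", "simulate_expression", "generate_dataset"]

# Per-edge regulation strength β is sampled uniformly from this range: the
# fraction of a target's synthesis under the regulator's control.  Strong
# regulation (β near 1) makes a TF knockout dominate its targets' synthesis,
# while the (1 − β) basal remainder keeps indirect effects attenuating.
_STRENGTH_RANGE = (0.8, 0.95)

# Hill threshold K is sampled uniformly from this range (on the scale of
# wild-type levels ~1) before being raised to the Hill exponent.  Thresholds
# well below wild-type levels put regulators in saturation, the standard
# picture for strong constitutive TFs: partial drops of a regulator barely
# move its targets, a full knockout silences them — which is what separates
# direct targets from indirect descendants in knockout data.
_K_RANGE = (0.05, 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the network and expression generator.

    Parameters
    ----------
    n_genes
        Number of genes G (≥ 2).
    edge_density
        Expected edges per gene; the generated network has ≈
        ``edge_density * n_genes`` edges.
    noise_sd
        Scale of the multiplicative log-normal measurement noise applied
        to steady-state levels (0 disables noise).
    knockdown_residual
        Fraction of synthesis remaining in a knocked-down gene; 0 is a
        null mutant.
    hill_coefficient
        Hill exponent of the regulation terms (≥ 1; 2 gives the usual
        mildly sigmoidal response).
    activation_prob
        Probability that an edge is activating rather than repressing.
    tf_fraction
        Fraction of genes that can act as regulators.  Transcription is
        controlled by a dedicated minority of transcription factors
        (roughly 5–10% of genes in *E. coli*); concentrating out-degree
        on a small TF set produces the hub-dominated topology of real
        regulatory networks, in which most regulations share a
        regulator with many others.
    cycle_prob
        Probability, per newly attached gene, of adding one back-edge
        that closes a short feedback loop; kept small so the topology
        stays predominantly tree-like.
    seed
        Master seed; network topology and expression noise use
        independent streams derived from it.
    """

    n_genes: int
    edge_density: float = 1.5
    noise_sd: float = 0.05
    knockdown_residual: float = 0.0
    hill_coefficient: float = 2.0
    activation_prob: float = 0.7
    tf_fraction: float = 0.2
    cycle_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be at least 2")
        if self.edge_density <= 0:
            raise ValueError("edge_density must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.knockdown_residual < 1:
            raise ValueError("knockdown_residual must be in [0, 1)")
        if self.hill_coefficient < 1:
            raise ValueError("hill_coefficient must be ≥ 1")
        if not 0 <= self.activation_prob <= 1:
            raise ValueError("activation_prob must be in [0, 1]")
        if not 0 < self.tf_fraction <= 1:
            raise ValueError("tf_fraction must be in (0, 1]")
        if not 0 <= self.cycle_prob <= 1:
            raise ValueError("cycle_prob must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per purpose (0=topology, 1=kinetics/noise)
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, stream]))


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_network(config: SimulationConfig) -> GeneNetwork:
    """Grow a random regulatory network by seeded preferential attachment.

    A minority of genes (``tf_fraction``, at least two) act as
    transcription factors; only they acquire out-edges.  Genes are added
    one at a time and each new gene receives ``1 + Poisson(edge_density
    − 1)`` incoming edges from already-present TFs chosen with
    probability proportional to (out-degree + 1), producing the
    heavy-tailed hub-regulator out-degree distribution of real
    transcriptional networks.  With probability ``cycle_prob`` a
    back-edge from a new TF to one of its regulators is added, so a few
    feedback loops can occur, but the structure stays predominantly
    acyclic and tree-like.
    """
    rng = _rng(config, 0)
    names = _gene_names(config.n_genes)
    n_tfs = max(2, round(config.tf_fraction * config.n_genes))
    out_degree = np.zeros(config.n_genes)
    edges: set[tuple[str, str]] = set()
    mean_extra = max(config.edge_density - 1.0, 0.0)
    for j in range(1, config.n_genes):
        n_avail = min(j, n_tfs)  # TFs are the lowest-indexed genes
        k = min(1 + rng.poisson(mean_extra), n_avail)
        weights = out_degree[:n_avail] + 1.0
        parents = rng.choice(n_avail, size=k, replace=False, p=weights / weights.sum())
        for p in parents:
            edges.add((names[p], names[j]))
            out_degree[p] += 1
        if j < n_tfs and config.cycle_prob > 0 and rng.random() < config.cycle_prob:
            back_to = int(parents[0])
            if (names[j], names[back_to]) not in edges:
                edges.add((names[j], names[back_to]))
                out_degree[j] += 1
    return GeneNetwork(tuple(names), frozenset(edges))


def _steady_state(
    reg_idx: np.ndarray,
    tgt_idx: np.ndarray,
    activating: np.ndarray,
    thresholds: np.ndarray,
    strengths: np.ndarray,
    basal: np.ndarray,
    hill: float,
    synth_scale: np.ndarray,
    x0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    damping: float = 0.5,
) -> np.ndarray:
    """Damped fixed-point iteration for x = synth_scale * b * Π(regulation terms).

    Edges are flat arrays (regulator index, target index, sign, Hill
    threshold K^h, strength β); the per-target product of regulation
    terms is accumulated in log space so each iteration is O(edges).
    """
    x = x0.copy()
    log_terms = np.empty(len(basal))
    for _ in range(max_iter):
        xh = np.power(x, hill)
        act = xh[reg_idx] / (thresholds + xh[reg_idx])
        # activators follow act, repressors 1 - act; (1 - β) is basal remainder
        term = (1.0 - strengths) + strengths * np.where(activating, act, 1.0 - act)
        log_terms.fill(0.0)
        np.add.at(log_terms, tgt_idx, np.log(term))
        target = synth_scale * basal * np.exp(log_terms)
        new_x = (1.0 - damping) * x + damping * target
        delta = np.abs(new_x - x).max()
        x = new_x
        if delta < tol:
            return x
    raise RuntimeError(
        "steady-state iteration failed to converge; the parameter set is pathological"
    )


def simulate_expression(network: GeneNetwork, config: SimulationConfig) -> ExpressionMatrix:
    """Steady-state expression for wild-type plus one knockdown per gene.

    Returns a G × (G + 1) matrix: column 0 is the wild-type steady
    state, column i (1-based) the steady state with gene i's synthesis
    scaled by ``knockdown_residual``.  Seeded multiplicative log-normal
    noise of scale ``noise_sd`` is applied, then the whole matrix is
    divided by its maximum entry so the dataset maximum is exactly one.
    """
    rng = _rng(config, 1)
    genes = list(network.genes)
    G = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    basal = rng.uniform(0.5, 1.5, size=G)
    # flat per-edge kinetic parameters, deterministic (sorted) edge order
    edges = sorted(network.edges)
    reg_idx = np.array([gene_idx[a] for a, _ in edges], dtype=int)
    tgt_idx = np.array([gene_idx[b] for _, b in edges], dtype=int)
    activating = np.empty(len(edges), dtype=bool)
    thresholds = np.empty(len(edges))
    strengths = np.empty(len(edges))
    for e in range(len(edges)):
        activating[e] = rng.random() < config.activation_prob
        thresholds[e] = rng.uniform(*_K_RANGE) ** config.hill_coefficient
        strengths[e] = rng.uniform(*_STRENGTH_RANGE)

    ones = np.ones(G)
    wt = _steady_state(
        reg_idx, tgt_idx, activating, thresholds, strengths, basal,
        config.hill_coefficient, ones, basal,
    )
    columns = [wt]
    for i in range(G):
        scale = np.ones(G)
        scale[i] = config.knockdown_residual
        columns.append(
            _steady_state(
                reg_idx, tgt_idx, activating, thresholds, strengths, basal,
                config.hill_coefficient, scale, wt,
            )
        )
    values = np.column_stack(columns)
    noise = rng.lognormal(mean=0.0, sigma=config.noise_sd, size=values.shape)
    values = values * noise
    peak = values.max()
    if peak <= 0:
        raise RuntimeError("degenerate simulation: all expression levels are zero")
    values = values / peak
    condition_ids = ("wt",) + tuple(f"kd_{g}" for g in genes)
    return ExpressionMatrix(tuple(genes), condition_ids, values)


def generate_dataset(config: SimulationConfig) -> tuple[GeneNetwork, ExpressionMatrix]:
    """Generate a matched (network, expression) pair from one config."""
    network = generate_network(config)
    return network, simulate_expression(network, config)
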