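import warnings

import numpy as np
import pytest

from pugrn import SimulationConfig, generate_dataset
from pugrn.datasets import chain_fixture, chain_network

# libsvm's internal Platt calibration is the intended behavior; sklearn 1.9
# deprecates the flag that enables it.
warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)


@pytest.fixture(scope="session")
def chain():
    """3-gene chain a -> b -> c with noiseless all-activating expression."""
    return chain_fixture(seed=0)


@pytest.fixture(scope="session")
def chain_net():
    return chain_network()


@pytest.fixture(scope="session")
def sim10():
    """A G=10 simulated dataset with default noise."""
    return generate_dataset(SimulationConfig(n_genes=10, seed=1))


def brute_force_closure(edges, genes):
    """Path-existence oracle: DFS from every node; self-pairs excluded."""
    adjacency = {g: set() for g in genes}
    for a, b in edges:
        adjacency[a].add(b)
    closed = set()
    for start in genes:
        seen = set()
        stack = list(adjacency[start])
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adjacency[node])
        closed.update((start, t) for t in seen if t != start)
    return closed


def brute_force_auroc(scores, truths):
    """All-pairs Mann-Whitney oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    truths = np.asarray(truths, int)
    pos = scores[truths == 1]
    neg = scores[truths == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_digraph(rng, max_nodes=8, edge_prob=0.3):
    n = rng.integers(2, max_nodes + 1)
    genes = [f"n{i}" for i in range(n)]
    edges = {
        (genes[i], genes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < edge_prob
    }
    return genes, edges
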