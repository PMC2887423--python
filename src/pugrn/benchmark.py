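"""Cross-validated benchmarking of the PU regulation classifiers.

Implements the simulated-data protocol: partition the ordered gene
pairs into known positives P, hidden positives Q and true negatives N;
split each stratum into k folds; train on k−1 folds (PosOnly/SVMOnly on
labeled vs unlabeled, PSEUDO-RANDOM on positives vs heuristic
negatives) and score the held-out fold against the gold standard, where
the true positives of fold i are P_i ∪ Q_i.  Metrics follow the
benchmark's conventions: precision = 1 and recall = 0 when nothing is
predicted; F is the balanced harmonic mean; AUROC is computed on raw
ranking scores (for PosOnly, the unclipped ratio, so its ranking — and
hence AUROC — coincides exactly with SVMOnly's).

Also provides the hyperparameter grid search over exponential C/γ
sequences, the factorial experiment sweep (network size × known
fraction × replicates), and the per-transcription-factor local-model
benchmark used with experimental compendia.
"""

from __future__ import annotations

import logging
import math
import time
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .expression import ExpressionMatrix, PairExample, build_pair_dataset, standardize_profiles
from .network import (
    GeneNetwork,
    LabelPartition,
    partition_edges,
    pseudo_random_negatives,
)
from .pu import (
    CEstimate,
    SvmConfig,
    fit_posonly,
    train_nontraditional,
    train_pseudo_random,
)

logger = logging.getLogger(__name__)

METHODS = ("posonly", "svmonly", "pseudorandom")

#: C and γ defaults per simulated network size (RBF C-SVC).
SIZE_DEFAULTS: dict[int, tuple[float, float]] = {
    10: (500.0, 0.05),
    50: (500.0, 0.01),
    100: (500.0, 0.005),
    500: (500.0, 0.001),
}

#: Defaults for the per-TF experimental mode (as used by SIRENE).
EXPERIMENTAL_CONFIG = SvmConfig(C=1000.0, gamma=1.0 / 128.0)

__all__ = [
    "ConfusionMatrix",
    "FoldResult",
    "BenchmarkResult",
    "stratified_kfold",
    "confusion_metrics",
    "f_measure",
    "auroc",
    "run_cv",
    "run_cv_multi",
    "grid_search",
    "default_parameter_grid",
    "default_svm_config",
    "experiment_sweep",
    "per_tf_benchmark",
    "results_to_frame",
    "SIZE_DEFAULTS",
    "EXPERIMENTAL_CONFIG",
    "METHODS",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class FoldResult:
    """Metrics of one cross-validation trial."""

    fold_index: int
    cm: ConfusionMatrix
    precision: float
    recall: float
    f_measure: float
    auroc: float


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-fold results and their means for one method on one configuration."""

    method: str
    network_size: int
    known_fraction: float
    network_seed: int
    label_seed: int
    folds: tuple[FoldResult, ...]
    mean_precision: float
    mean_recall: float
    mean_f: float
    mean_auroc: float

    @classmethod
    def from_folds(
        cls,
        method: str,
        network_size: int,
        known_fraction: float,
        network_seed: int,
        label_seed: int,
        folds: Sequence[FoldResult],
    ) -> "BenchmarkResult":
        return cls(
            method=method,
            network_size=network_size,
            known_fraction=known_fraction,
            network_seed=network_seed,
            label_seed=label_seed,
            folds=tuple(folds),
            mean_precision=float(np.mean([f.precision for f in folds])),
            mean_recall=float(np.mean([f.recall for f in folds])),
            mean_f=float(np.mean([f.f_measure for f in folds])),
            mean_auroc=float(np.mean([f.auroc for f in folds])),
        )


def _stable_hash(name: str) -> int:
    """Process-independent 31-bit hash of a string identifier."""
    return zlib.crc32(name.encode("utf-8")) % 2**31


def _child_seed(*keys: int) -> int:
    """Deterministic sub-seed derived from a tuple of integer keys."""
    return int(np.random.SeedSequence([int(k) % 2**31 for k in keys]).generate_state(1)[0] % 2**31)


def _split_stratum(items: Sequence, k: int, rng: np.random.Generator) -> list[list]:
    """Shuffle a stratum and split it into k chunks with sizes differing ≤ 1."""
    items = sorted(items)
    if items and len(items) < k:
        raise ValueError(f"stratum of size {len(items)} cannot be split into {k} folds")
    order = rng.permutation(len(items))
    return [[items[i] for i in chunk] for chunk in np.array_split(order, k)]


def stratified_kfold(partition: LabelPartition, k: int, seed: int = 0) -> list[LabelPartition]:
    """Split each of P, Q, N independently into k seeded folds.

    Returns k fold slices (as LabelPartitions over the same genes) that
    are pairwise disjoint and jointly cover the originals.  Raises if a
    nonempty stratum has fewer than k members.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(int(seed) % 2**31)
    parts_p = _split_stratum(sorted(partition.P), k, rng)
    parts_q = _split_stratum(sorted(partition.Q), k, rng)
    parts_n = _split_stratum(sorted(partition.N), k, rng)
    return [
        LabelPartition(partition.genes, frozenset(p), frozenset(q), frozenset(n))
        for p, q, n in zip(parts_p, parts_q, parts_n)
    ]


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """Precision and recall with the no-prediction convention.

    When no pair is predicted positive (TP + FP = 0) precision is taken
    to be 1 and recall 0.
    """
    if cm.tp + cm.fp == 0:
        return 1.0, 0.0
    precision = cm.tp / (cm.tp + cm.fp)
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else 0.0
    return precision, recall


def f_measure(precision: float, recall: float) -> float:
    """Balanced F: harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def auroc(scores: Sequence[float], truths: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney / trapezoidal form)."""
    truths = np.asarray(truths, dtype=int)
    if truths.min() == truths.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(truths, np.asarray(scores, dtype=float)))


def _fold_metrics(
    fold_index: int,
    probs: np.ndarray,
    ranking_scores: np.ndarray,
    y_true: np.ndarray,
    threshold: float = 0.5,
) -> FoldResult:
    pred = probs > threshold
    pos = y_true == 1
    cm = ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )
    precision, recall = confusion_metrics(cm)
    auc = auroc(ranking_scores, y_true) if pos.any() and (~pos).any() else float("nan")
    return FoldResult(fold_index, cm, precision, recall, f_measure(precision, recall), auc)


def run_cv_multi(
    network: GeneNetwork,
    expr: ExpressionMatrix,
    known_fraction: float,
    methods: Sequence[str],
    config: SvmConfig,
    k: int = 10,
    seed: int = 0,
    random_fraction: float = 0.1,
    max_unlabeled: int | None = None,
) -> dict[str, BenchmarkResult]:
    """Stratified k-fold cross-validation for several methods on shared folds.

    PosOnly and SVMOnly share the same base non-traditional classifier
    per fold (their training data and labels are identical); PosOnly
    additionally estimates the labeling frequency c on a held-out slice
    of the training split and divides its scores by it.  PSEUDO-RANDOM
    retrains on known positives versus transitive-closure negatives
    drawn from the training pairs.

    When the smallest nonempty stratum has fewer than k members, the
    fold count is lowered to that size so every fold keeps at least one
    member of each nonempty stratum.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    label_seed = _child_seed(seed, 1)
    fold_seed = _child_seed(seed, 2)
    partition = partition_edges(network, known_fraction, seed=label_seed)
    stratum_sizes = [len(s) for s in (partition.P, partition.Q, partition.N) if s]
    k_eff = min([k] + stratum_sizes)
    if k_eff < 2:
        raise ValueError("smallest nonempty stratum has fewer than 2 members")
    folds = stratified_kfold(partition, k_eff, seed=fold_seed)

    examples = build_pair_dataset(expr, partition)
    by_pair = {ex.pair: ex for ex in examples}
    all_pairs = [ex.pair for ex in examples]

    fold_results: dict[str, list[FoldResult]] = {m: [] for m in methods}
    for i, fold in enumerate(folds):
        t0 = time.perf_counter()
        test_pairs = fold.P | fold.Q | fold.N
        train_ex = [by_pair[p] for p in all_pairs if p not in test_pairs]
        fold_train_seed = _child_seed(seed, 3, i)
        if max_unlabeled is not None:
            labeled = [ex for ex in train_ex if ex.s == 1]
            unlabeled = [ex for ex in train_ex if ex.s == 0]
            if len(unlabeled) > max_unlabeled:
                rng = np.random.default_rng(_child_seed(seed, 4, i))
                keep = rng.choice(len(unlabeled), size=max_unlabeled, replace=False)
                train_ex = labeled + [unlabeled[j] for j in sorted(keep)]
        test_ex = [by_pair[p] for p in all_pairs if p in test_pairs]
        X_test = np.vstack([ex.x for ex in test_ex])
        y_true = np.array([ex.y for ex in test_ex], dtype=int)

        base_scores: np.ndarray | None = None
        c_est: CEstimate | None = None
        if "posonly" in methods:
            clf, c_est = fit_posonly(train_ex, config, seed=fold_train_seed)
            base_scores = clf.score_many(X_test)
        elif "svmonly" in methods:
            clf = train_nontraditional(train_ex, config, seed=fold_train_seed)
            base_scores = clf.score_many(X_test)

        for method in methods:
            if method == "posonly":
                assert base_scores is not None and c_est is not None
                unclipped = base_scores / c_est.c
                probs = np.minimum(1.0, unclipped)
                fr = _fold_metrics(i, probs, unclipped, y_true)
            elif method == "svmonly":
                assert base_scores is not None
                fr = _fold_metrics(i, base_scores, base_scores, y_true)
            else:  # pseudorandom
                train_pairs = {ex.pair for ex in train_ex}
                p_train = frozenset(ex.pair for ex in train_ex if ex.s == 1)
                known_net = GeneNetwork(network.genes, p_train)
                candidates = pseudo_random_negatives(
                    known_net, network.genes, random_fraction, seed=fold_train_seed
                )
                negs = candidates & train_pairs
                pclf = train_pseudo_random(train_ex, negs, config, seed=fold_train_seed)
                pscores = pclf.score_many(X_test)
                fr = _fold_metrics(i, pscores, pscores, y_true)
            fold_results[method].append(fr)
        logger.info(
            "fold %d/%d (%s, G=%d, P=%.0f%%) done in %.2fs",
            i + 1, k_eff, "+".join(methods), network.n_genes,
            100 * known_fraction, time.perf_counter() - t0,
        )

    return {
        m: BenchmarkResult.from_folds(
            m, network.n_genes, known_fraction, -1, label_seed, fold_results[m]
        )
        for m in methods
    }


def run_cv(
    network: GeneNetwork,
    expr: ExpressionMatrix,
    known_fraction: float,
    method: str,
    config: SvmConfig,
    k: int = 10,
    seed: int = 0,
    random_fraction: float = 0.1,
    max_unlabeled: int | None = None,
) -> BenchmarkResult:
    """Stratified k-fold cross-validation for one method (see run_cv_multi)."""
    return run_cv_multi(
        network, expr, known_fraction, [method], config,
        k=k, seed=seed, random_fraction=random_fraction, max_unlabeled=max_unlabeled,
    )[method]


def default_parameter_grid(full: bool = False) -> tuple[list[float], list[float]]:
    """Exponential C and γ grids: C ∈ 2^-5..2^15, γ ∈ 2^-13..2^3.

    The default grid steps every second power of two (×4); ``full``
    switches to every power of two (×2).
    """
    step = 1 if full else 2
    c_grid = [2.0**e for e in range(-5, 16, step)]
    gamma_grid = [2.0**e for e in range(-13, 4, step)]
    return c_grid, gamma_grid


def default_svm_config(n_genes: int) -> SvmConfig:
    """Size-keyed (C, γ) defaults; nearest tabulated size wins."""
    best = min(SIZE_DEFAULTS, key=lambda g: abs(math.log(g) - math.log(n_genes)))
    C, gamma = SIZE_DEFAULTS[best]
    return SvmConfig(C=C, gamma=gamma)


def grid_search(
    network: GeneNetwork,
    expr: ExpressionMatrix,
    method: str,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    seed: int = 0,
    known_fraction: float = 0.5,
    k: int = 10,
) -> SvmConfig:
    """Pick (C, γ) maximizing mean F over a stratified k-fold CV.

    Ties break toward smaller C, then smaller γ.
    """
    if C_grid is None or gamma_grid is None:
        default_c, default_g = default_parameter_grid()
        C_grid = C_grid if C_grid is not None else default_c
        gamma_grid = gamma_grid if gamma_grid is not None else default_g
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be nonempty")
    best: tuple[float, SvmConfig] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            config = SvmConfig(C=C, gamma=gamma)
            result = run_cv(network, expr, known_fraction, method, config, k=k, seed=seed)
            if best is None or result.mean_f > best[0]:
                best = (result.mean_f, config)
            logger.info("grid C=%g gamma=%g mean F=%.4f", C, gamma, result.mean_f)
    assert best is not None
    return best[1]


def results_to_frame(results: Iterable[BenchmarkResult]) -> pd.DataFrame:
    """Flatten BenchmarkResults into a tidy per-fold DataFrame."""
    rows = []
    for r in results:
        for f in r.folds:
            rows.append(
                {
                    "method": r.method,
                    "network_size": r.network_size,
                    "known_fraction": r.known_fraction,
                    "network_seed": r.network_seed,
                    "label_seed": r.label_seed,
                    "fold": f.fold_index,
                    "tp": f.cm.tp,
                    "fp": f.cm.fp,
                    "fn": f.cm.fn,
                    "tn": f.cm.tn,
                    "precision": f.precision,
                    "recall": f.recall,
                    "f_measure": f.f_measure,
                    "auroc": f.auroc,
                }
            )
    columns = [
        "method", "network_size", "known_fraction", "network_seed", "label_seed",
        "fold", "tp", "fp", "fn", "tn", "precision", "recall", "f_measure", "auroc",
    ]
    return pd.DataFrame(rows, columns=columns)


def experiment_sweep(
    sizes: Sequence[int],
    fractions: Sequence[float],
    n_networks: int = 3,
    n_label_draws: int = 3,
    methods: Sequence[str] = METHODS,
    base_seed: int = 0,
    k: int = 10,
    noise_sd: float = 0.05,
    edge_density: float = 1.5,
    config_by_size: Mapping[int, SvmConfig] | None = None,
    max_unlabeled: int | None = None,
) -> pd.DataFrame:
    """Full factorial sweep: size × network replicate × fraction × label draw.

    For each network size, ``n_networks`` networks are generated; each
    is benchmarked at every known fraction with ``n_label_draws``
    independent label selections, running all requested methods on
    shared folds.  Returns a tidy per-fold DataFrame.
    """
    from .simulate import SimulationConfig, generate_dataset

    frames = []
    for size in sizes:
        config = (
            config_by_size[size]
            if config_by_size is not None and size in config_by_size
            else default_svm_config(size)
        )
        for net_i in range(n_networks):
            net_seed = _child_seed(base_seed, size, net_i)
            network, expr = generate_dataset(
                SimulationConfig(
                    n_genes=size, edge_density=edge_density, noise_sd=noise_sd, seed=net_seed
                )
            )
            for frac_i, fraction in enumerate(fractions):
                for draw_j in range(n_label_draws):
                    cv_seed = _child_seed(base_seed, size, net_i, frac_i, draw_j)
                    results = run_cv_multi(
                        network, expr, fraction, methods, config,
                        k=k, seed=cv_seed, max_unlabeled=max_unlabeled,
                    )
                    frame = results_to_frame(results.values())
                    frame["network_seed"] = net_seed
                    frame["label_draw"] = draw_j
                    frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out


def per_tf_benchmark(
    expr: ExpressionMatrix,
    regulons: Mapping[str, Iterable[str]],
    known_fraction: float,
    config: SvmConfig = EXPERIMENTAL_CONFIG,
    seed: int = 0,
    k: int = 3,
    methods: Sequence[str] = ("posonly", "svmonly"),
) -> pd.DataFrame:
    """Per-transcription-factor local-model benchmark (experimental mode).

    For each TF the examples are single genes, featured by their own
    standardized expression profile; positives are the genes the TF is
    known to regulate.  A seeded ``known_fraction`` of the regulon plays
    the labeled set P*, the rest of the regulon is hidden (Q*), and all
    remaining genes are N*.  A stratified ``k``-fold (3 by default)
    cross-validation yields precision/recall per fold; because Q* genes
    counted as negatives may in truth be regulated, the reported PR* and
    RC* are lower bounds on the actual precision and recall.

    PSEUDO-RANDOM is a pair-graph heuristic and has no local-model
    counterpart here; requesting it raises.
    """
    if not 0 < known_fraction <= 1:
        raise ValueError("known_fraction must be in (0, 1]")
    for m in methods:
        if m == "pseudorandom":
            raise NotImplementedError(
                "the transitive-closure heuristic is defined on the global pair "
                "graph and has no per-TF local-model analogue"
            )
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    std = standardize_profiles(expr)
    gene_set = set(expr.gene_ids)
    rows = []
    for tf in sorted(regulons):
        regulon = set(regulons[tf]) - {tf}
        if regulon - gene_set:
            raise ValueError(f"regulon of {tf!r} contains genes absent from the matrix")
        candidates = sorted(gene_set - {tf})
        if len(regulon) < k:
            raise ValueError(f"regulon of {tf!r} has fewer than {k} genes")
        rng = np.random.default_rng(_child_seed(seed, _stable_hash(tf)))
        regulon_sorted = sorted(regulon)
        n_known = max(1, round(known_fraction * len(regulon_sorted)))
        p_star = {regulon_sorted[i] for i in rng.choice(len(regulon_sorted), n_known, replace=False)}
        q_star = regulon - p_star
        n_star = set(candidates) - regulon

        strata = [sorted(p_star), sorted(q_star), sorted(n_star)]
        fold_rng = np.random.default_rng(_child_seed(seed, _stable_hash(tf), 1))
        fold_sets = [_split_stratum(s, k, fold_rng) if s else [[] for _ in range(k)] for s in strata]

        examples = {
            g: PairExample(
                tf, g, std.row(g), y=1 if g in regulon else 0, s=1 if g in p_star else 0
            )
            for g in candidates
        }
        for i in range(k):
            test_genes = set(fold_sets[0][i]) | set(fold_sets[1][i]) | set(fold_sets[2][i])
            train_ex = [examples[g] for g in candidates if g not in test_genes]
            test_ex = [examples[g] for g in candidates if g in test_genes]
            X_test = np.vstack([ex.x for ex in test_ex])
            y_true = np.array([ex.y for ex in test_ex], dtype=int)
            fold_seed = _child_seed(seed, _stable_hash(tf), 2, i)
            base = None
            c_est = None
            if "posonly" in methods:
                clf, c_est = fit_posonly(train_ex, config, seed=fold_seed)
                base = clf.score_many(X_test)
            elif "svmonly" in methods:
                clf = train_nontraditional(train_ex, config, seed=fold_seed)
                base = clf.score_many(X_test)
            for method in methods:
                if method == "posonly":
                    assert base is not None and c_est is not None
                    unclipped = base / c_est.c
                    fr = _fold_metrics(i, np.minimum(1.0, unclipped), unclipped, y_true)
                else:
                    assert base is not None
                    fr = _fold_metrics(i, base, base, y_true)
                rows.append(
                    {
                        "tf": tf,
                        "method": method,
                        "known_fraction": known_fraction,
                        "fold": i,
                        "tp": fr.cm.tp,
                        "fp": fr.cm.fp,
                        "fn": fr.cm.fn,
                        "tn": fr.cm.tn,
                        "precision": fr.precision,
                        "recall": fr.recall,
                        "f_measure": fr.f_measure,
                        "auroc": fr.auroc,
                    }
                )
    return pd.DataFrame(rows)
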