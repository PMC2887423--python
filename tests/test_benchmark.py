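"""Cross-validation machinery, metric conventions, and sweeps."""

import numpy as np
import pytest

from pugrn import SimulationConfig, SvmConfig, generate_dataset
from pugrn.benchmark import (
    ConfusionMatrix,
    auroc,
    confusion_metrics,
    default_parameter_grid,
    default_svm_config,
    experiment_sweep,
    f_measure,
    grid_search,
    per_tf_benchmark,
    results_to_frame,
    run_cv,
    run_cv_multi,
    stratified_kfold,
)
from pugrn.datasets import regulon_fixture
from pugrn.network import GeneNetwork, partition_edges

from .conftest import brute_force_auroc

FAST = SvmConfig(C=500, gamma=0.05)


def _partition(n_genes=10, n_edges=20, known=0.5, seed=0):
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i}" for i in range(n_genes))
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_genes, 2)
        if i != j:
            edges.add((genes[i], genes[j]))
    return partition_edges(GeneNetwork(genes, frozenset(edges)), known, seed=seed)


class TestStratifiedKfold:
    def test_even_split_sizes(self):
        part = _partition(known=0.5)
        folds = stratified_kfold(part, 10, seed=1)
        assert [len(f.P) for f in folds] == [1] * 10
        sizes = sorted(len(f.N) for f in folds)
        assert max(sizes) - min(sizes) <= 1

    def test_folds_partition_each_stratum(self):
        part = _partition(known=0.6, seed=3)
        folds = stratified_kfold(part, 4, seed=2)
        for stratum in ("P", "Q", "N"):
            pieces = [getattr(f, stratum) for f in folds]
            assert frozenset().union(*pieces) == getattr(part, stratum)
            assert sum(len(p) for p in pieces) == len(getattr(part, stratum))

    def test_remainder_distributed(self):
        part = _partition(n_edges=26, known=0.5, seed=4)  # |P|=13
        folds = stratified_kfold(part, 10, seed=0)
        sizes = [len(f.P) for f in folds]
        assert set(sizes) <= {1, 2} and sum(sizes) == 13

    def test_small_stratum_rejected(self):
        part = _partition(n_edges=6, known=0.5)  # |P|=3 < k
        with pytest.raises(ValueError, match="cannot be split"):
            stratified_kfold(part, 10, seed=0)


class TestMetricConventions:
    def test_no_prediction_convention(self):
        precision, recall = confusion_metrics(ConfusionMatrix(0, 0, 5, 10))
        assert (precision, recall) == (1.0, 0.0)

    def test_arithmetic(self):
        precision, recall = confusion_metrics(ConfusionMatrix(3, 1, 2, 10))
        assert (precision, recall) == (0.75, 0.6)

    def test_perfect(self):
        assert confusion_metrics(ConfusionMatrix(5, 0, 0, 10)) == (1.0, 1.0)

    @pytest.mark.parametrize(
        "precision, recall, expected",
        [(1, 1, 1.0), (1, 0, 0.0), (0, 0, 0.0), (0.75, 0.6, 0.6666667)],
    )
    def test_f_measure(self, precision, recall, expected):
        assert f_measure(precision, recall) == pytest.approx(expected, abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_textbook_example(self):
        assert auroc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            n = rng.integers(4, 51)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            truths = rng.integers(0, 2, n)
            if truths.min() == truths.max():
                continue
            assert auroc(scores, truths) == pytest.approx(
                brute_force_auroc(scores, truths), abs=1e-12
            )


class TestRunCv:
    def test_deterministic(self, sim10):
        network, expr = sim10
        a = run_cv(network, expr, 0.5, "posonly", FAST, k=5, seed=9)
        b = run_cv(network, expr, 0.5, "posonly", FAST, k=5, seed=9)
        assert a == b

    def test_metric_identities(self, sim10):
        network, expr = sim10
        result = run_cv(network, expr, 0.5, "svmonly", FAST, k=5, seed=2)
        for fold in result.folds:
            precision, recall = confusion_metrics(fold.cm)
            assert fold.precision == precision and fold.recall == recall
            assert fold.f_measure == pytest.approx(f_measure(precision, recall), abs=1e-12)

    def test_fold_counts_reconstruct_strata(self, sim10):
        network, expr = sim10
        result = run_cv(network, expr, 0.5, "svmonly", FAST, k=5, seed=2)
        n_pairs = 10 * 9
        total = sum(f.cm.tp + f.cm.fp + f.cm.fn + f.cm.tn for f in result.folds)
        assert total == n_pairs
        n_true = sum(f.cm.tp + f.cm.fn for f in result.folds)
        assert n_true == len(network.edges)

    def test_posonly_svmonly_share_auroc(self, sim10):
        network, expr = sim10
        res = run_cv_multi(network, expr, 0.5, ["posonly", "svmonly"], FAST, k=5, seed=4)
        for fp, fs in zip(res["posonly"].folds, res["svmonly"].folds):
            assert fp.auroc == fs.auroc

    def test_fold_count_lowered_to_smallest_stratum(self, sim10):
        network, expr = sim10  # 12 edges; known 0.5 -> |P|=6 < 10
        result = run_cv(network, expr, 0.5, "svmonly", FAST, k=10, seed=1)
        assert len(result.folds) == 6

    def test_unknown_method_rejected(self, sim10):
        network, expr = sim10
        with pytest.raises(ValueError, match="unknown method"):
            run_cv(network, expr, 0.5, "oracle", FAST, k=5, seed=0)


class TestGridSearch:
    def test_default_grid_bounds(self):
        c_grid, g_grid = default_parameter_grid()
        assert c_grid[0] == 2.0**-5 and c_grid[-1] == 2.0**15
        assert g_grid[0] == 2.0**-13 and g_grid[-1] == 2.0**3
        full_c, full_g = default_parameter_grid(full=True)
        assert len(full_c) == 21 and len(full_g) == 17

    def test_size_keyed_defaults(self):
        assert (default_svm_config(10).C, default_svm_config(10).gamma) == (500.0, 0.05)
        assert default_svm_config(500).gamma == 0.001
        assert default_svm_config(60).gamma == 0.01  # nearest tabulated size

    def test_picks_best_on_tiny_grid(self, sim10):
        network, expr = sim10
        best = grid_search(
            network, expr, "svmonly",
            C_grid=[500.0], gamma_grid=[1e-8, 0.05],
            seed=0, known_fraction=1.0, k=5,
        )
        # a vanishing bandwidth cannot separate anything; the sane value wins
        assert best.gamma == 0.05


class TestExperimentSweep:
    def test_row_count_and_columns(self):
        df = experiment_sweep(
            sizes=[10], fractions=[0.5, 1.0], n_networks=2, n_label_draws=1,
            methods=("posonly", "svmonly"), base_seed=0, k=3,
        )
        # size x net x fraction x draw x method, k folds each
        assert len(df) == 1 * 2 * 2 * 1 * 2 * 3
        assert {"method", "known_fraction", "f_measure", "auroc"} <= set(df.columns)

    def test_results_frame_round_trip(self, sim10):
        network, expr = sim10
        res = run_cv(network, expr, 0.5, "svmonly", FAST, k=5, seed=2)
        df = results_to_frame([res])
        assert len(df) == 5
        assert df.f_measure.mean() == pytest.approx(res.mean_f)


class TestPerTfBenchmark:
    def test_planted_regulon_is_recovered(self):
        expr, regulons = regulon_fixture(seed=0)
        recalls = []
        for seed in range(10):
            df = per_tf_benchmark(expr, regulons, 1.0, seed=seed, methods=("posonly",))
            recalls.append(df.recall.mean())
        assert np.mean(recalls) > 0.5

    def test_full_knowledge_has_no_hidden_positives(self):
        expr, regulons = regulon_fixture(seed=1)
        df = per_tf_benchmark(expr, regulons, 1.0, seed=0, methods=("svmonly",))
        # with Q* empty every test positive is a real one, so PR* is exact:
        # fold counts must cover the whole regulon
        assert (df.tp + df.fn).sum() == len(regulons["tf0"])

    def test_deterministic(self):
        expr, regulons = regulon_fixture(seed=2)
        a = per_tf_benchmark(expr, regulons, 0.7, seed=3)
        b = per_tf_benchmark(expr, regulons, 0.7, seed=3)
        assert a.equals(b)

    def test_small_regulon_rejected(self):
        expr, _ = regulon_fixture(seed=0)
        with pytest.raises(ValueError, match="fewer than"):
            per_tf_benchmark(expr, {"tf0": {"t01", "t02"}}, 1.0, seed=0)

    def test_pseudorandom_not_applicable(self):
        expr, regulons = regulon_fixture(seed=0)
        with pytest.raises(NotImplementedError):
            per_tf_benchmark(expr, regulons, 1.0, seed=0, methods=("pseudorandom",))
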