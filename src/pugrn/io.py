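"""Tab-separated readers and writers for networks, expression and results.

All on-disk formats are plain TSV:

* expression — first row condition ids, first column gene ids, floats;
* edge lists — two columns ``regulator<TAB>target``, ``#`` comments;
* regulons — two columns ``TF<TAB>target_gene``;
* benchmark results — tidy CSV, one row per (method, size, fraction,
  seeds, fold).

Parse failures raise distinct exception types that name the offending
line, so a malformed input is diagnosable from the error alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "MalformedRowError",
    "NonNumericError",
    "DuplicateIdError",
    "SelfLoopError",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_regulons",
    "write_results",
    "make_fixtures",
]


class ParseError(ValueError):
    """A TSV input could not be parsed."""


class MalformedRowError(ParseError):
    """A row has the wrong number of columns."""


class NonNumericError(ParseError):
    """A cell expected to be numeric is not."""


class DuplicateIdError(ParseError):
    """A gene identifier occurs more than once."""


class SelfLoopError(ParseError):
    """An edge list contains a self-regulation."""


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × conditions TSV (header row of condition ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    condition_ids = header[1:]
    if not condition_ids:
        raise MalformedRowError(f"{path}: line 1: no condition columns")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(condition_ids) + 1:
            raise MalformedRowError(
                f"{path}: line {lineno}: expected {len(condition_ids) + 1} columns, "
                f"got {len(cells)}"
            )
        gene = cells[0]
        if gene in gene_ids:
            raise DuplicateIdError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as err:
            raise NonNumericError(f"{path}: line {lineno}: {err}") from None
        gene_ids.append(gene)
    return ExpressionMatrix(tuple(gene_ids), tuple(condition_ids), np.array(rows))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.condition_ids) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_edge_list(path: str | Path, genes: list[str] | None = None) -> GeneNetwork:
    """Read a directed edge list (``regulator<TAB>target`` per line).

    ``#`` comment lines are skipped; duplicate edges are collapsed with
    a warning; self-loops are rejected, naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise MalformedRowError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(cells)}"
                )
            a, b = cells
            if a == b:
                raise SelfLoopError(f"{path}: line {lineno}: self-regulation {a!r} -> {b!r}")
            if (a, b) in edges:
                logger.warning("%s: line %d: duplicate edge %r -> %r", path, lineno, a, b)
            edges.add((a, b))
    return GeneNetwork.from_edges(edges, genes=genes)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write edges sorted lexicographically, for diff-stable output."""
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def read_regulons(path: str | Path) -> dict[str, set[str]]:
    """Read a ``TF<TAB>target`` list into a {TF: targets} mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    regulons: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise MalformedRowError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(cells)}"
                )
            regulons.setdefault(cells[0], set()).add(cells[1])
    return regulons


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy results table as CSV, deterministically ordered.

    Rows are sorted by all non-metric key columns and floats rendered
    with 6 significant digits, so identical runs yield byte-identical
    files.
    """
    df = table.copy()
    key_cols = [c for c in df.columns if df[c].dtype == object or c in
                ("method", "tf", "network_size", "known_fraction", "network_seed",
                 "label_seed", "label_draw", "fold")]
    if len(df):
        df = df.sort_values([c for c in key_cols if c in df.columns], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.6g")


def make_fixtures(outdir: str | Path, seed: int = 0) -> None:
    """Write the small deterministic test assets used across the suite.

    Emits the 3-gene chain (network + noiseless expression), a G=10
    simulated dataset, Gaussian PU samples at labeling frequencies 0.3,
    0.5 and 0.9, and the per-TF regulon fixture.  Byte-identical under
    the same seed.
    """
    from .datasets import chain_fixture, gaussian_pu_sample, regulon_fixture
    from .simulate import SimulationConfig, generate_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net, expr = chain_fixture(seed=seed)
    write_edge_list(net, outdir / "chain.net.tsv")
    write_expression(expr, outdir / "chain.expr.tsv")

    network, sim_expr = generate_dataset(SimulationConfig(n_genes=10, seed=seed))
    write_edge_list(network, outdir / "sim10.net.tsv")
    write_expression(sim_expr, outdir / "sim10.expr.tsv")

    for c_true in (0.3, 0.5, 0.9):
        sample = gaussian_pu_sample(n=2000, c_true=c_true, seed=seed)
        frame = pd.DataFrame(sample.X, columns=[f"x{i}" for i in range(sample.X.shape[1])])
        frame["y"] = sample.y
        frame["s"] = sample.s
        frame["posterior"] = sample.posterior
        frame.to_csv(outdir / f"gaussian_c{int(c_true * 100):02d}.tsv", sep="\t",
                     index=False, float_format="%.6g")

    reg_expr, regulons = regulon_fixture(seed=seed)
    write_expression(reg_expr, outdir / "regulon.expr.tsv")
    with open(outdir / "regulon.tsv", "w") as fh:
        for tf in sorted(regulons):
            for target in sorted(regulons[tf]):
                fh.write(f"{tf}\t{target}\n")
    logger.info("fixtures written to %s", outdir)
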