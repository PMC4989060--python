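"""Readers and writers for the pipeline's plain-text formats.

Formats:

* expression TSV — header row of sample ids, first column gene id;
* STRING-dialect TSV — ``gene1 TAB gene2 TAB combined_score`` with an
  integer score in [0, 1000] (a header line is tolerated);
* GMT — ``set_name TAB description TAB gene1 TAB gene2 ...``;
* specific-network TSV — ``gene1, gene2, status_normal, status_cancer``;
* module membership TSV — ``gene, module_id``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    FunctionalNetwork,
    GeneModule,
    GeneSetCollection,
    ModuleSet,
    SpecificNetwork,
    gene_pair,
)
from .errors import FormatError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"


def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Load an expression TSV into an :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by their mean (with a warning);
    genes containing missing values are dropped (logged). At least 3
    samples are required.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expression matrix needs >= 3 samples, found {df.shape[1]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: malformed header, duplicate sample ids {dups[:5]}")

    # locate non-numeric cells precisely before coercing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        row_number = df.index.get_loc(gene) + 2  # +1 header, +1 one-based
        raise FormatError(
            f"{path}: non-numeric value at gene {gene!r}, sample {col!r} (line {row_number})"
        )

    if numeric.index.has_duplicates:
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.warning(
            "%s: %d duplicated gene id(s) collapsed by mean (e.g. %s)",
            path, len(dups), dups[:3],
        )
        numeric = numeric.groupby(level=0, sort=False).mean()

    with_na = numeric.index[numeric.isna().any(axis=1)].tolist()
    if with_na:
        logger.warning(
            "%s: dropping %d gene(s) with missing values (e.g. %s)",
            path, len(with_na), with_na[:3],
        )
        numeric = numeric.dropna(axis=0)
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric, condition=condition)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_string_network(path: str | Path) -> FunctionalNetwork:
    """Parse a STRING-dialect edge list (gene1, gene2, combined score)."""
    path = Path(path)
    edges: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {line_no}: expected 3 fields, got {len(fields)}")
            a, b, raw = fields[0], fields[1], fields[2]
            if line_no == 1 and not raw.lstrip("-").isdigit():
                continue  # header line
            try:
                score = int(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {line_no}: combined score {raw!r} is not an integer"
                ) from exc
            if not 0 <= score <= 1000:
                raise FormatError(f"{path}: line {line_no}: score {score} outside [0, 1000]")
            if a == b:
                logger.warning("%s: line %d: dropping self-edge %s", path, line_no, a)
                continue
            edges.append((a, b, score))
    return FunctionalNetwork.from_edges(edges)


def write_string_network(network: FunctionalNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tcombined_score\n")
        for (a, b), s in sorted(network.scores.items()):
            fh.write(f"{a}\t{b}\t{s}\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse GMT gene sets; the universe defaults to the union of all sets."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_no}: GMT rows need name, description and >=1 gene"
                )
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}: line {line_no}: gene set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}: line {line_no}: duplicate set name {name!r}")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    if universe is None:
        universe = set().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def write_specific_network(network: SpecificNetwork, path: str | Path) -> None:
    network.to_frame().to_csv(path, sep="\t", index=False)


def read_specific_network(path: str | Path) -> SpecificNetwork:
    import networkx as nx

    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
    expected = ["gene1", "gene2", "status_normal", "status_cancer"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = gene_pair(row.gene1, row.gene2)
        graph.add_edge(a, b, status_normal=int(row.status_normal),
                       status_cancer=int(row.status_cancer))
    return SpecificNetwork(graph)


def write_modules(mods: ModuleSet, path: str | Path) -> None:
    rows = sorted(
        (g, m.module_id) for m in mods for g in m.genes
    )
    pd.DataFrame(rows, columns=["gene", "module_id"]).to_csv(path, sep="\t", index=False)


def read_modules(path: str | Path, partition_seed: int = 0, algorithm_tag: str = "file") -> ModuleSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene", "module_id"]:
        raise FormatError(f"{path}: expected columns ['gene', 'module_id']")
    grouped = df.groupby("module_id")["gene"].apply(set)
    modules = [GeneModule(mid, frozenset(genes)) for mid, genes in sorted(grouped.items())]
    modules.sort(key=lambda m: (-len(m.genes), min(m.genes)))
    return ModuleSet(modules, partition_seed=partition_seed, algorithm_tag=algorithm_tag)
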