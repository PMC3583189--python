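"""Tabular I/O for the IXP pipeline.

All pipeline artifacts are plain tab-separated text: interaction edge
lists (``geneA\\tgeneB[\\tconfidence]``), gene x sample expression
matrices with a sample-ID header row, sample label files, node-ordering
files (``gene\\tposition``), feature matrices (samples x positions) and
reordered adjacency matrices.  Lines starting with ``#`` are provenance
comments and are ignored by every reader.

Gene symbols are canonicalized on read: upper-cased and whitespace
stripped.  Self-interactions are dropped (and counted), duplicate
unordered gene pairs are collapsed keeping the maximum confidence, and
duplicate expression rows (e.g. multiple probes for one gene) are
collapsed by arithmetic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "ExpressionMatrix",
    "SeedGeneSet",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "read_seed_genes",
    "read_ordering",
    "write_ordering",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_reordered_adjacency",
]


class ParseError(ValueError):
    """Malformed input file (carries file and line context in the message)."""


def canonical_symbol(symbol: str) -> str:
    """Canonical gene symbol: stripped of surrounding whitespace, upper-case."""
    return symbol.strip().upper()


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One undirected scored interaction; endpoints stored sorted."""

    gene_a: str
    gene_b: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        a, b = canonical_symbol(self.gene_a), canonical_symbol(self.gene_b)
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not a valid record")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with optional two-class sample labels.

    ``values`` is a pandas DataFrame indexed by unique canonical gene
    symbols with sample IDs as columns.  ``labels`` maps every sample to
    0 or 1; ``class_names`` records which original class name was
    encoded as 0 and which as 1.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    class_names: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids after collapse: {list(dupes)[:5]}")
        if self.labels is not None:
            missing = [s for s in self.values.columns if s not in self.labels.index]
            if missing:
                raise ValueError(f"samples missing from labels: {missing}")
            bad = set(self.labels.unique()) - {0, 1}
            if bad:
                raise ValueError(f"labels must be encoded 0/1, found {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def label_vector(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("expression matrix has no sample labels")
        return self.labels.loc[self.values.columns].to_numpy()


@dataclass
class SeedGeneSet:
    """Disease seed genes with class annotation (I: both sources, II: one)."""

    genes: set[str] = field(default_factory=set)
    klass: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = {canonical_symbol(g) for g in self.genes}
        self.klass = {canonical_symbol(g): k for g, k in self.klass.items()}
        stray = set(self.klass) - self.genes
        if stray:
            raise ValueError(f"class annotation for unknown seeds: {sorted(stray)}")
        bad = set(self.klass.values()) - {"I", "II"}
        if bad:
            raise ValueError(f"seed class must be 'I' or 'II', found {bad}")


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, min_confidence: float = 0.0) -> list[InteractionRecord]:
    """Read a 2- or 3-column tab-separated interaction file.

    Self-loops are dropped (counted in the log), duplicate unordered
    pairs collapsed keeping the maximum confidence, and records with
    confidence below ``min_confidence`` filtered out.  The returned list
    is sorted canonically, so it does not depend on input line order.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise ParseError(
                f"{path}: line {lineno}: expected 2 or 3 tab-separated columns, "
                f"got {len(fields)}"
            )
        a, b = canonical_symbol(fields[0]), canonical_symbol(fields[1])
        if len(fields) == 3:
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: bad confidence {fields[2]!r}"
                ) from exc
        else:
            conf = 1.0
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        best[key] = max(best.get(key, 0.0), conf)
    if n_self:
        log.info("dropped %d self-interactions from %s", n_self, path)
    records = [
        InteractionRecord(a, b, c) for (a, b), c in best.items() if c >= min_confidence
    ]
    if not records:
        raise ParseError(f"{path}: no edges left after filtering (min_confidence={min_confidence})")
    return sorted(records)


def write_edge_list(records: Iterable[InteractionRecord], path: str | Path,
                    header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for rec in sorted(records):
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.confidence:g}\n")


def _read_labels(label_path: str | Path,
                 class_order: Sequence[str] | None = None) -> tuple[pd.Series, tuple[str, str]]:
    """Parse a two-column sample\\tclass file.

    The class encoded 0 is, in precedence order: ``class_order[0]`` if
    given, the first class of a ``sample\\tclassA/classB`` header, else
    the class of the first data row.
    """
    rows: list[tuple[str, str]] = []
    header_order: list[str] | None = None
    first = True
    for lineno, line in _data_lines(label_path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2:
            raise ParseError(
                f"{label_path}: line {lineno}: expected 2 columns, got {len(fields)}"
            )
        if first:
            first = False
            if fields[0].lower() in {"sample", "sample_id", "id"}:
                if "/" in fields[1]:
                    header_order = [c.strip() for c in fields[1].split("/")]
                continue
        rows.append((fields[0], fields[1]))
    if not rows:
        raise ParseError(f"{label_path}: no sample labels found")
    classes_seen: list[str] = []
    for _, cls in rows:
        if cls not in classes_seen:
            classes_seen.append(cls)
    if len(classes_seen) != 2:
        raise ParseError(
            f"{label_path}: expected exactly two classes, found {classes_seen}"
        )
    if class_order is not None:
        order = list(class_order)
    elif header_order is not None:
        order = header_order
    else:
        order = classes_seen
    if sorted(order) != sorted(classes_seen):
        raise ParseError(
            f"{label_path}: class order {order} does not match classes {classes_seen}"
        )
    encoding = {order[0]: 0, order[1]: 1}
    labels = pd.Series({s: encoding[c] for s, c in rows}, dtype=int)
    return labels, (order[0], order[1])


def read_expression(path: str | Path, label_path: str | Path | None = None,
                    class_order: Sequence[str] | None = None,
                    collapse: str = "mean") -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample IDs, first column = gene).

    Duplicate gene rows are collapsed by arithmetic ``mean`` (or ``max``
    / ``first``), controlled by ``collapse``.  When ``label_path`` is
    given, every sample must have a label; labels are encoded {0, 1}
    with the class named first (see :func:`_read_labels`) as 0.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    df.index = [canonical_symbol(str(g)) for g in df.index]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[int(np.argmax(bad.to_numpy()))]
            raise ParseError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at gene {df.index[loc[0]]!r}, "
            f"sample {df.columns[loc[1]]!r}"
        )
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows in %s by %s", n_dup, path, collapse)
        grouped = df.groupby(level=0, sort=False)
        if collapse == "mean":
            df = grouped.mean()
        elif collapse == "max":
            df = grouped.max()
        elif collapse == "first":
            df = grouped.first()
        else:
            raise ValueError(f"unknown collapse policy {collapse!r}")
    labels = class_names = None
    if label_path is not None:
        labels, class_names = _read_labels(label_path, class_order)
        missing = [s for s in df.columns if s not in labels.index]
        if missing:
            raise ParseError(f"{label_path}: no label for sample(s) {missing}")
    return ExpressionMatrix(values=df.astype(float), labels=labels, class_names=class_names)


def read_seed_genes(path: str | Path) -> SeedGeneSet:
    """Read a seed file: one gene per line, optional second column I/II."""
    genes: set[str] = set()
    klass: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) not in (1, 2):
            raise ParseError(f"{path}: line {lineno}: expected 1 or 2 columns")
        g = canonical_symbol(fields[0])
        genes.add(g)
        if len(fields) == 2 and fields[1]:
            if fields[1] not in ("I", "II"):
                raise ParseError(
                    f"{path}: line {lineno}: seed class must be I or II, got {fields[1]!r}"
                )
            klass[g] = fields[1]
    if not genes:
        raise ParseError(f"{path}: no seed genes found")
    return SeedGeneSet(genes=genes, klass=klass)


# ---------------------------------------------------------------------------
# orderings, feature matrices, adjacency export


def _position_mapping(ordering) -> Mapping[str, int]:
    return ordering.position if hasattr(ordering, "position") else ordering


def write_ordering(ordering, path: str | Path, header: str | None = None) -> None:
    """Write ``gene\\tposition`` lines sorted by position."""
    pos = _position_mapping(ordering)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for gene, p in sorted(pos.items(), key=lambda kv: kv[1]):
            fh.write(f"{gene}\t{p}\n")


def read_ordering(path: str | Path) -> dict[str, int]:
    pos: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        gene = canonical_symbol(fields[0])
        try:
            pos[gene] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad position {fields[1]!r}") from exc
    if not pos:
        raise ParseError(f"{path}: empty ordering file")
    if sorted(pos.values()) != list(range(1, len(pos) + 1)):
        raise ParseError(f"{path}: positions are not a bijection onto 1..{len(pos)}")
    return pos


def write_feature_matrix(fm, path: str | Path) -> None:
    """Write a samples x positions feature matrix with a provenance header."""
    prov = getattr(fm, "provenance", None)
    values: pd.DataFrame = fm.values if hasattr(fm, "provenance") else fm
    with open(path, "w") as fh:
        if prov:
            items = "; ".join(f"{k}={v}" for k, v in prov.items())
            fh.write(f"# provenance: {items}\n")
        values.to_csv(fh, sep="\t", index_label="sample", float_format="%.17g")


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    provenance: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            for item in first.partition(":")[2].split(";"):
                if "=" in item:
                    k, _, v = item.strip().partition("=")
                    provenance[k] = v
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.columns = [int(c) for c in df.columns]
    return df, provenance


def write_reordered_adjacency(net, ordering, path: str | Path,
                              use_confidence: bool = False) -> None:
    """Export the N x N adjacency matrix with rows/columns in ordering position.

    Cells are 0/1, or the edge confidence when ``use_confidence`` is set.
    Supports re-plotting the reordered adjacency heatmap.
    """
    pos = _position_mapping(ordering)
    genes_by_pos = [g for g, _ in sorted(pos.items(), key=lambda kv: kv[1])]
    n = len(genes_by_pos)
    mat = np.zeros((n, n))
    index = {g: i for i, g in enumerate(genes_by_pos)}
    for u, v, data in net.graph.edges(data=True):
        i, j = index[u], index[v]
        val = float(data.get("confidence", 1.0)) if use_confidence else 1.0
        mat[i, j] = mat[j, i] = val
    df = pd.DataFrame(mat, index=genes_by_pos, columns=genes_by_pos)
    df.to_csv(path, sep="\t", float_format="%g")
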