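"""Data model and plain-text / XML readers and writers.

Every stage of the pipeline exchanges artifacts through minimal plain-text
formats: tab-delimited matrices (genes x samples), two-column cluster files
(gene TAB module) and an XML document holding the per-module hierarchical
condition trees.  The readers here are strict inverses of the writers at the
level of ids and values (not bytes).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

import numpy as np

logger = logging.getLogger(__name__)

MISSING_SENTINELS = {"", "NA"}


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _check_ids(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with missing entries as NaN."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.sample_ids, "sample")
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 2:
            raise ValueError("need at least 1 gene and 2 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def standardized(self) -> "ExpressionMatrix":
        """Per-gene z-score (missing entries ignored and preserved)."""
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(self.values, axis=1, keepdims=True)
            sd = np.nanstd(self.values, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), (self.values - mu) / sd
        )


@dataclass
class RegulatorMatrix:
    """Candidate-regulator profiles on the same samples as the expression data.

    ``kind`` is ``"continuous"`` or ``"discrete"``; discrete profiles are
    integer-coded but stored as floats so missing entries stay representable.
    """

    regulator_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regulator_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ids")
        _check_ids(self.regulator_ids, "regulator")
        _check_ids(self.sample_ids, "sample")
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"kind must be continuous|discrete, got {self.kind!r}")
        if self.kind == "discrete":
            vals = self.values[~np.isnan(self.values)]
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("discrete regulator matrix has non-integer values")

    @property
    def n_regulators(self) -> int:
        return len(self.regulator_ids)

    def align_samples(self, sample_ids: Sequence[str]) -> "RegulatorMatrix":
        """Restrict and reorder columns to the expression matrix sample order.

        Samples absent on either side are dropped with a warning; the model
        requires both data types on the same samples.
        """
        have = set(self.sample_ids)
        shared = [s for s in sample_ids if s in have]
        if not shared:
            raise ValueError("no shared samples between matrices")
        dropped = (len(self.sample_ids) - len(shared)) + (len(sample_ids) - len(shared))
        if dropped:
            logger.warning(
                "dropping %d non-shared samples when aligning regulator matrix",
                dropped,
            )
        idx = [self.sample_ids.index(s) for s in shared]
        return RegulatorMatrix(
            list(self.regulator_ids), shared, self.values[:, idx], self.kind
        )


def _read_table(path) -> tuple[list[str], list[tuple[str, list[str]]]]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    ncol = len(rows[1]) - 1
    # header may or may not carry a corner label above the id column
    if len(header) == ncol + 1:
        samples = header[1:]
    elif len(header) == ncol:
        samples = header
    else:
        raise FormatError(f"{path}: header has {len(header)} fields, data rows {ncol + 1}")
    data = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol + 1:
            raise FormatError(f"{path}: ragged row at line {lineno}")
        data.append((row[0], row[1:]))
    return samples, data


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    if cell in MISSING_SENTINELS:
        return math.nan
    return float(cell)


def read_matrix(path) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix.

    First row holds sample ids, first column gene ids.  Empty cells or the
    literal ``NA`` mark missing values; they are flagged (NaN), never imputed.
    """
    samples, data = _read_table(path)
    genes = [g for g, _ in data]
    values = np.array([[_parse_cell(c) for c in row] for _, row in data])
    return ExpressionMatrix(genes, samples, values)


def write_matrix(matrix: ExpressionMatrix | RegulatorMatrix, path) -> None:
    ids = (
        matrix.gene_ids
        if isinstance(matrix, ExpressionMatrix)
        else matrix.regulator_ids
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", *matrix.sample_ids])
        for i, gid in enumerate(ids):
            row = [gid] + [
                "NA" if math.isnan(v) else repr(float(v)) for v in matrix.values[i]
            ]
            w.writerow(row)


def read_regulator_matrix(path, kind: str = "continuous") -> RegulatorMatrix:
    samples, data = _read_table(path)
    regs = [r for r, _ in data]
    values = np.array([[_parse_cell(c) for c in row] for _, row in data])
    return RegulatorMatrix(regs, samples, values, kind)


# ---------------------------------------------------------------------------
# clusterings
# ---------------------------------------------------------------------------


@dataclass
class TwoWayClustering:
    """Gene -> module partition plus a per-module partition of the samples.

    ``condition_partition[k]`` maps every sample id to a condition-cluster
    index for module ``k``; ``score`` is the total Bayesian score of the
    two-way clustering.
    """

    module_of: dict[str, int]
    condition_partition: dict[int, dict[str, int]]
    score: float = math.nan

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def modules(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for g, k in self.module_of.items():
            out.setdefault(k, []).append(g)
        return [out[k] for k in sorted(out)]

    def genes_in_module(self, k: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == k]


def _dense_relabel(labels: Iterable[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
    return mapping


def read_cluster_file(path) -> dict[str, int]:
    """Read a two-column gene TAB module file.

    Module labels are re-indexed densely 0..K-1 in first-appearance order;
    arbitrary string labels are accepted.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not any(c.strip() for c in row):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: expected 2 columns at line {lineno}")
            pairs.append((row[0], row[1]))
    seen: dict[str, str] = {}
    for g, m in pairs:
        if g in seen and seen[g] != m:
            raise FormatError(f"gene {g!r} listed in modules {seen[g]!r} and {m!r}")
        seen[g] = m
    relabel = _dense_relabel(m for _, m in pairs)
    return {g: relabel[m] for g, m in seen.items()}


def write_cluster_file(module_of: Mapping[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g, k in module_of.items():
            w.writerow([g, k])


# ---------------------------------------------------------------------------
# condition trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a binary condition tree.

    Leaves hold a non-empty set of sample ids; internal nodes hold exactly two
    children, the Bayesian merge score of joining them, and optionally the
    regulator assignments attached at that split.
    """

    samples: list[str] | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    level: int = 0
    merge_score: float | None = None
    regulators: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.samples is not None

    def all_samples(self) -> list[str]:
        if self.is_leaf:
            return list(self.samples)  # type: ignore[arg-type]
        return self.left.all_samples() + self.right.all_samples()  # type: ignore[union-attr]

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()  # type: ignore[union-attr]

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return (
            [self]
            + self.left.internal_nodes()  # type: ignore[union-attr]
            + self.right.internal_nodes()  # type: ignore[union-attr]
        )


@dataclass
class ConditionTree:
    """Binary hierarchical tree of sample sets for one module."""

    module: int
    root: TreeNode

    def __post_init__(self) -> None:
        self._validate(self.root, 0)
        samples = self.root.all_samples()
        if len(samples) != len(set(samples)):
            raise ValueError("leaves do not partition the sample set")

    @staticmethod
    def _validate(node: TreeNode, level: int) -> None:
        node.level = level
        if node.is_leaf:
            if not node.samples:
                raise ValueError("empty leaf")
            return
        if node.left is None or node.right is None:
            raise ValueError("internal node must have exactly 2 children")
        ConditionTree._validate(node.left, level + 1)
        ConditionTree._validate(node.right, level + 1)

    def leaf_partition(self) -> dict[str, int]:
        part: dict[str, int] = {}
        for i, leaf in enumerate(self.root.leaves()):
            for s in leaf.samples:  # type: ignore[union-attr]
                part[s] = i
        return part


def _node_to_xml(node: TreeNode) -> ET.Element:
    if node.is_leaf:
        el = ET.Element("leaf", level=str(node.level))
        for s in node.samples:  # type: ignore[union-attr]
            ET.SubElement(el, "sample", id=s)
        return el
    el = ET.Element("split", level=str(node.level))
    if node.merge_score is not None:
        el.set("score", repr(float(node.merge_score)))
    for a in node.regulators:
        ET.SubElement(
            el,
            "regulator",
            id=a.regulator_id,
            z=repr(float(a.split_value)),
            orientation=str(a.orientation),
            p=repr(float(a.posterior)),
        )
    el.append(_node_to_xml(node.left))  # type: ignore[arg-type]
    el.append(_node_to_xml(node.right))  # type: ignore[arg-type]
    return el


def write_trees_xml(trees: Mapping[int, ConditionTree], path) -> None:
    """Serialize condition trees, one ``<module>`` element per module."""
    root = ET.Element("condition_trees")
    for k in sorted(trees):
        mod = ET.SubElement(root, "module", id=str(k))
        mod.append(_node_to_xml(trees[k].root))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def _node_from_xml(el: ET.Element, path: str) -> TreeNode:
    from .regulators import RegulatorAssignment  # local import avoids a cycle

    if el.tag == "leaf":
        samples = [c.get("id") for c in el if c.tag == "sample"]
        if not samples or any(s is None for s in samples):
            raise FormatError(f"malformed leaf at {path}")
        return TreeNode(samples=list(samples), level=int(el.get("level", "0")))
    if el.tag != "split":
        raise FormatError(f"unexpected element <{el.tag}> at {path}")
    children = [c for c in el if c.tag in ("leaf", "split")]
    if len(children) != 2:
        raise FormatError(
            f"<split> at {path} has {len(children)} children, expected 2"
        )
    node = TreeNode(
        left=_node_from_xml(children[0], path + "/" + children[0].tag),
        right=_node_from_xml(children[1], path + "/" + children[1].tag),
        level=int(el.get("level", "0")),
        merge_score=float(el.get("score")) if el.get("score") is not None else None,
    )
    for c in el:
        if c.tag == "regulator":
            node.regulators.append(
                RegulatorAssignment(
                    regulator_id=c.get("id"),
                    module=-1,
                    node_id="",
                    split_value=float(c.get("z")),
                    orientation=int(c.get("orientation")),
                    posterior=float(c.get("p")),
                    level=int(el.get("level", "0")),
                )
            )
    return node


def read_trees_xml(path) -> dict[int, ConditionTree]:
    try:
        doc = ET.parse(path)
    except ET.ParseError as e:
        raise FormatError(f"{path}: malformed XML: {e}") from e
    root = doc.getroot()
    if root.tag != "condition_trees":
        raise FormatError(f"{path}: root element is <{root.tag}>")
    trees: dict[int, ConditionTree] = {}
    for mod in root:
        if mod.tag != "module":
            raise FormatError(f"{path}: unexpected element <{mod.tag}> under root")
        k = int(mod.get("id"))
        kids = list(mod)
        if len(kids) != 1:
            raise FormatError(f"{path}: module {k} must hold exactly one tree")
        tree = ConditionTree(k, _node_from_xml(kids[0], f"module[{k}]"))
        for a in tree.root.internal_nodes():
            for r in a.regulators:
                r.module = k
        trees[k] = tree
    return trees


def read_regulator_list(path) -> list[str]:
    """One regulator id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_regulator_scores(scores, path) -> None:
    """Three-column TSV: module, regulator, score (descending by score)."""
    rows = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for (reg, mod), s in rows:
            w.writerow([mod, reg, repr(float(s))])
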