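"""Readers and writers for DREAM-style tab-separated interchange files.

Four file kinds are handled, all plain TSV with a ``.`` decimal separator
and no quoting:

* expression matrix — header row of gene identifiers, one sample per row;
* transcription-factor list — one identifier per line;
* gold standard — ``regulator<TAB>target<TAB>label`` with label 0 or 1;
* ranked predictions — ``regulator<TAB>target<TAB>score`` in descending
  score order.

Self-regulatory interactions are excluded throughout: a gold standard may
not assert a positive self-loop and a ranked edge list may not contain a
self-pair.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "RegulatorSet",
    "GoldStandard",
    "RankedEdgeList",
    "read_expression",
    "read_tf_list",
    "read_gold_standard",
    "read_ranked_edges",
    "write_expression",
    "write_tf_list",
    "write_gold_standard",
    "write_ranked_edges",
]


class FormatError(ValueError):
    """A file violates the expected TSV dialect or an invariant of its type."""


def _try_float(token: str) -> float | None:
    try:
        return float(token)
    except ValueError:
        return None


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes table of expression values.

    ``values[s, g]`` is the expression of gene ``gene_ids[g]`` in sample
    ``s``. Gene identifiers are unique and non-empty; every value is finite.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(g) for g in self.gene_ids)
        object.__setattr__(self, "gene_ids", ids)
        if not ids:
            raise FormatError("expression matrix has no genes")
        if any(g == "" for g in ids):
            raise FormatError("empty gene identifier")
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for g in ids:
                if g in seen:
                    raise FormatError(f"duplicate gene identifier: {g!r}")
                seen.add(g)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if values.shape[1] != len(ids):
            raise FormatError(
                f"{values.shape[1]} value columns for {len(ids)} gene identifiers"
            )
        if values.shape[0] == 0:
            raise FormatError("expression matrix has no samples")
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def sample_count(self) -> int:
        return self.values.shape[0]

    @property
    def gene_count(self) -> int:
        return self.values.shape[1]

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.index_of(gene_id)]


@dataclass(frozen=True)
class RegulatorSet:
    """Ordered collection of candidate regulators (transcription factors)."""

    tf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(g) for g in self.tf_ids)
        if not ids:
            raise FormatError("regulator set is empty")
        if len(set(ids)) != len(ids):
            raise FormatError("regulator set contains duplicates")
        object.__setattr__(self, "tf_ids", ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.tf_ids)

    def __len__(self) -> int:
        return len(self.tf_ids)


@dataclass(frozen=True)
class GoldStandard:
    """Labeled regulator->target pairs; pairs not listed are implied negatives."""

    labeled_pairs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (reg, tgt), label in self.labeled_pairs.items():
            if label not in (0, 1):
                raise FormatError(f"label for ({reg}, {tgt}) must be 0 or 1, got {label!r}")
            if reg == tgt and label == 1:
                raise FormatError(
                    f"self-loop {reg}->{tgt} labeled 1: self-regulatory interactions are ignored"
                )

    @property
    def positives(self) -> set[tuple[str, str]]:
        return {p for p, v in self.labeled_pairs.items() if v == 1}

    def label(self, regulator: str, target: str) -> int:
        """Label of a pair; pairs absent from the file count as negatives."""
        return self.labeled_pairs.get((regulator, target), 0)


@dataclass(frozen=True)
class RankedEdgeList:
    """Directed (regulator, target, score) triples in non-increasing score order."""

    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        edges = tuple((str(r), str(t), float(s)) for r, t, s in self.edges)
        seen: set[tuple[str, str]] = set()
        prev = math.inf
        for reg, tgt, score in edges:
            if reg == tgt:
                raise FormatError(f"self-pair {reg}->{tgt} in ranked edge list")
            if (reg, tgt) in seen:
                raise FormatError(f"duplicate pair {reg}->{tgt} in ranked edge list")
            seen.add((reg, tgt))
            if not math.isfinite(score):
                raise FormatError(f"non-finite score for {reg}->{tgt}")
            if score > prev:
                raise FormatError("ranked edge list scores are not non-increasing")
            prev = score
        object.__setattr__(self, "edges", edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read an expression TSV: header of gene identifiers, one sample per row.

    A header line that parses entirely as numbers is rejected rather than
    silently auto-naming genes.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    if all(_try_float(tok) is not None for tok in header):
        raise FormatError(
            f"{path}: header row parses entirely as numbers; "
            "an identifier header is required"
        )
    n_genes = len(header)
    rows = []
    for r, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        if len(cells) != n_genes:
            raise FormatError(
                f"{path}: row {r} has {len(cells)} cells, expected {n_genes}"
            )
        row = []
        for c, cell in enumerate(cells, start=1):
            val = _try_float(cell)
            if val is None:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {r}, column {c}"
                )
            row.append(val)
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: expression file has a header but no samples")
    return ExpressionMatrix(gene_ids=tuple(header), values=np.array(rows, dtype=float))


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(expr.gene_ids) + "\n")
        for row in expr.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_tf_list(path: str | os.PathLike) -> RegulatorSet:
    """Read a TF list, one identifier per line; blank lines ignored.

    Duplicates are collapsed to their first occurrence with a logged warning.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = [ln.strip() for ln in fh]
    ids: list[str] = []
    seen: set[str] = set()
    for tok in raw:
        if tok == "":
            continue
        if tok in seen:
            logger.warning("duplicate transcription factor %r in %s; keeping first", tok, path)
            continue
        seen.add(tok)
        ids.append(tok)
    if not ids:
        raise FormatError(f"{path}: transcription-factor list is empty")
    return RegulatorSet(tf_ids=tuple(ids))


def write_tf_list(tfs: RegulatorSet, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf in tfs.tf_ids:
            fh.write(tf + "\n")


def read_gold_standard(path: str | os.PathLike) -> GoldStandard:
    """Read a 3-column gold standard: regulator, target, label in {0, 1}."""
    pairs: dict[tuple[str, str], int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for r, line in enumerate(fh.read().splitlines(), start=1):
            if line == "":
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}: row {r} has {len(cells)} columns, expected 3")
            reg, tgt, lab = cells
            if lab not in ("0", "1"):
                raise FormatError(f"{path}: row {r}: label must be 0 or 1, got {lab!r}")
            label = int(lab)
            if reg == tgt and label == 1:
                raise FormatError(
                    f"{path}: row {r}: self-loop {reg}->{tgt} labeled 1; "
                    "self-regulatory interactions are ignored"
                )
            pairs[(reg, tgt)] = label
    return GoldStandard(labeled_pairs=pairs)


def write_gold_standard(gold: GoldStandard, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (reg, tgt), label in gold.labeled_pairs.items():
            fh.write(f"{reg}\t{tgt}\t{label}\n")


def read_ranked_edges(path: str | os.PathLike) -> RankedEdgeList:
    """Read a prediction file: regulator, target, score, descending order."""
    edges: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for r, line in enumerate(fh.read().splitlines(), start=1):
            if line == "":
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}: row {r} has {len(cells)} columns, expected 3")
            score = _try_float(cells[2])
            if score is None:
                raise FormatError(f"{path}: row {r}: non-numeric score {cells[2]!r}")
            edges.append((cells[0], cells[1], score))
    return RankedEdgeList(edges=tuple(edges))


def write_ranked_edges(edges: RankedEdgeList, path: str | os.PathLike) -> None:
    """Write a ranked edge list; scores serialized at full repr precision.

    Round-trips through :func:`read_ranked_edges` bit-exactly for the
    identifiers and to full float precision for the scores.
    """
    if not isinstance(edges, RankedEdgeList):
        edges = RankedEdgeList(edges=tuple(edges))
    with open(path, "w", encoding="utf-8") as fh:
        for reg, tgt, score in edges:
            fh.write(f"{reg}\t{tgt}\t{repr(score)}\n")
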