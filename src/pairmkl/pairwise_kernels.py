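"""Pairwise kernels: similarity between unordered pairs of nodes.

Supervised link prediction classifies *pairs* of nodes, so the kernel must
compare a candidate pair (a, b) with another pair (c, d).  Five standard
constructions lift a node kernel K to a pair kernel:

P1 (TPPK, tensor product)   K(a,c)K(b,d) + K(a,d)K(b,c)
P2 (direct sum)             K(a,c) + K(a,d) + K(b,c) + K(b,d)
P3 (MLPK, metric learning)  (K(a,c) - K(a,d) - K(b,c) + K(b,d))^2
P4 (cosine of differences)  the P3 bracket normalized by the feature-space
                            norms of Phi(a)-Phi(b) and Phi(c)-Phi(d)
P5 (CSPK, Cartesian product) indicator-gated sum
                            K(a,c)I(b=d) + K(b,d)I(a=c) + K(a,d)I(b=c) + K(b,c)I(a=d)

All five are PSD whenever K is PSD *and* pairs are consistently oriented.
P4 is antisymmetric under swapping the two nodes inside one pair (its
implicit feature vector is a unit difference vector), so pairs are
canonicalized to index_a < index_b at ingest; under a fixed orientation the
P4 Gram is a Gram of unit vectors, hence PSD.

Pairs are unordered distinct nodes: self-pairs are rejected (P4 is
undefined on them, and link semantics concern distinct genes), and
duplicates after canonicalization are an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import DataError
from .node_kernels import NodeKernel

#: Default number of Gram rows assembled per block (memory guard).
DEFAULT_BLOCK_SIZE = 1024


class PairwiseKernelKind(str, Enum):
    """The closed enumeration of supported pairwise kernel constructions."""

    P1 = "P1"  # tensor product pairwise kernel (TPPK)
    P2 = "P2"  # symmetric direct sum
    P3 = "P3"  # metric learning pairwise kernel (MLPK)
    P4 = "P4"  # cosine similarity of feature-space difference vectors
    P5 = "P5"  # Cartesian product pairwise kernel (CSPK)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_KINDS = tuple(PairwiseKernelKind)


@dataclass
class PairSet:
    """Canonicalized unordered node pairs with optional +/-1 link labels.

    ``pairs`` is an integer array of shape (n, 2) indexing into a node
    kernel's node list, with ``pairs[:, 0] < pairs[:, 1]``; ``labels`` is
    None or an aligned +/-1 integer vector (+1 link, -1 nonlink).
    """

    pairs: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise DataError(f"pairs must have shape (n, 2), got {pairs.shape}")
        if (pairs[:, 0] == pairs[:, 1]).any():
            i = int(np.flatnonzero(pairs[:, 0] == pairs[:, 1])[0])
            raise DataError(f"self-pair at row {i}: ({pairs[i, 0]}, {pairs[i, 0]})")
        # canonicalize: smaller index first
        self.pairs = np.sort(pairs, axis=1)
        key = self.pairs[:, 0] * (self.pairs.max() + 2) + self.pairs[:, 1]
        if np.unique(key).size != len(key):
            raise DataError("duplicate pairs after canonicalization")
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int64)
            if labels.shape != (len(self.pairs),):
                raise DataError("labels length does not match pairs")
            if not np.isin(labels, (-1, 1)).all():
                raise DataError("labels must be -1 or +1")
            self.labels = labels

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, idx) -> "PairSet":
        idx = np.asarray(idx)
        return PairSet(self.pairs[idx],
                       None if self.labels is None else self.labels[idx])

    def node_id_pairs(self, node_ids: list[str]) -> list[tuple[str, str]]:
        return [(node_ids[a], node_ids[b]) for a, b in self.pairs]


@dataclass(frozen=True)
class BaseKernelSpec:
    """One base kernel of a composite: a pairwise construction applied to a named data kernel."""

    kind: PairwiseKernelKind
    kernel_name: str

    def label(self) -> str:
        return f"{self.kind.value}({self.kernel_name})"


def read_pair_tsv(path, node_ids) -> PairSet:
    """Read a pair file: ``node_a<TAB>node_b[<TAB>label]`` per row.

    The label column, when present, must be -1 or 1 on every row.  Node
    IDs are resolved against ``node_ids`` (a list of IDs or a
    :class:`NodeKernel`); unknown IDs are an error.
    """
    if isinstance(node_ids, NodeKernel):
        node_ids = node_ids.node_ids
    index = {str(nid): i for i, nid in enumerate(node_ids)}
    pairs: list[tuple[int, int]] = []
    labels: list[int] = []
    n_cols = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if n_cols is None:
                if len(fields) not in (2, 3):
                    raise DataError(f"{path}:{lineno}: expected 2 or 3 columns")
                n_cols = len(fields)
            if len(fields) != n_cols:
                raise DataError(f"{path}:{lineno}: inconsistent column count")
            try:
                a = index[fields[0]]
                b = index[fields[1]]
            except KeyError as exc:
                raise DataError(f"{path}:{lineno}: unknown node ID {exc}") from exc
            pairs.append((a, b))
            if n_cols == 3:
                try:
                    y = int(fields[2])
                except ValueError:
                    raise DataError(f"{path}:{lineno}: non-integer label '{fields[2]}'")
                if y not in (-1, 1):
                    raise DataError(f"{path}:{lineno}: label must be -1 or 1, got {y}")
                labels.append(y)
    if not pairs:
        raise DataError(f"{path}: no pairs")
    return PairSet(np.array(pairs), np.array(labels) if labels else None)


def write_pair_tsv(pair_set: PairSet, node_ids: list[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (a, b) in enumerate(pair_set.pairs):
            row = f"{node_ids[a]}\t{node_ids[b]}"
            if pair_set.labels is not None:
                row += f"\t{pair_set.labels[i]}"
            fh.write(row + "\n")


def pairwise_value(kind: PairwiseKernelKind, kernel: NodeKernel,
                   pair_a: tuple[int, int], pair_b: tuple[int, int]) -> float:
    """Evaluate one pairwise kernel entry between two canonicalized pairs."""
    rows = PairSet(np.array([pair_a]))
    cols = PairSet(np.array([pair_b]))
    return float(build_pairwise_gram(kind, kernel, rows, cols)[0, 0])


def _p4_denominators(K: np.ndarray, pairs: np.ndarray, name: str,
                     node_ids: list[str]) -> np.ndarray:
    a, b = pairs[:, 0], pairs[:, 1]
    d = K[a, a] - 2.0 * K[a, b] + K[b, b]
    scale = max(float(np.abs(np.diag(K)).max()), 1.0)
    bad = np.where(d <= 1e-12 * scale)[0]
    if bad.size:
        i = int(bad[0])
        raise DataError(
            f"P4 on kernel '{name}': zero feature-space difference norm for pair "
            f"({node_ids[pairs[i, 0]]}, {node_ids[pairs[i, 1]]}) — the two nodes are "
            "kernel-identical"
        )
    return d


def build_pairwise_gram(kind: PairwiseKernelKind, kernel: NodeKernel,
                        rows: PairSet, cols: PairSet | None = None,
                        block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
    """Assemble the |rows| x |cols| pairwise Gram matrix.

    ``cols=None`` means ``cols = rows`` (a square training Gram).  Assembly
    proceeds in row blocks of ``block_size``; results are independent of
    the block size.
    """
    kind = PairwiseKernelKind(kind)
    if cols is None:
        cols = rows
    K = kernel.matrix
    m = K.shape[0]
    for ps, tag in ((rows, "rows"), (cols, "cols")):
        if ps.pairs.size and ps.pairs.max() >= m:
            raise DataError(f"{tag}: pair index {int(ps.pairs.max())} out of range "
                            f"for kernel '{kernel.name}' with {m} nodes")
    if block_size < 1:
        raise DataError("block_size must be >= 1")

    c, d = cols.pairs[:, 0], cols.pairs[:, 1]
    if kind is PairwiseKernelKind.P4:
        row_den = _p4_denominators(K, rows.pairs, kernel.name, kernel.node_ids)
        col_den = (row_den if cols is rows
                   else _p4_denominators(K, cols.pairs, kernel.name, kernel.node_ids))

    out = np.empty((len(rows), len(cols)))
    for start in range(0, len(rows), block_size):
        stop = min(start + block_size, len(rows))
        a = rows.pairs[start:stop, 0]
        b = rows.pairs[start:stop, 1]
        Kac = K[np.ix_(a, c)]
        Kad = K[np.ix_(a, d)]
        Kbc = K[np.ix_(b, c)]
        Kbd = K[np.ix_(b, d)]
        if kind is PairwiseKernelKind.P1:
            blk = Kac * Kbd + Kad * Kbc
        elif kind is PairwiseKernelKind.P2:
            blk = Kac + Kad + Kbc + Kbd
        elif kind is PairwiseKernelKind.P3:
            diff = Kac - Kad - Kbc + Kbd
            blk = diff * diff
        elif kind is PairwiseKernelKind.P4:
            diff = Kac - Kad - Kbc + Kbd
            blk = diff / np.sqrt(np.outer(row_den[start:stop], col_den))
        else:  # P5: indicators compare node indices, not kernel rows
            blk = (Kac * (b[:, None] == d[None, :])
                   + Kbd * (a[:, None] == c[None, :])
                   + Kad * (b[:, None] == c[None, :])
                   + Kbc * (a[:, None] == d[None, :]))
        out[start:stop] = blk
    return out
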