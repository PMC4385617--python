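"""Node-level data kernels: loading, validation, and cosine normalization.

A *node kernel* (also called a data kernel) is a symmetric positive
semidefinite similarity matrix over named nodes (genes, proteins): the
building block from which pairwise kernels over candidate links are
constructed.  Typical real examples are sequence kernels (spectrum, motif,
Pfam) and diffusion kernels over experimental interaction networks; here
they are simply square TSV matrices with a node-ID header.

Finite-precision kernels (diffusion kernels especially) routinely carry
tiny negative eigenvalues, so positive semidefiniteness is enforced with a
relative tolerance and violations warn by default; a ``strict`` flag turns
them into errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Relative PSD tolerance: smallest eigenvalue must be >= -PSD_TOL * largest.
PSD_TOL = 1e-8

#: Relative symmetry tolerance on |K_ij - K_ji|.
SYMMETRY_TOL = 1e-9


class PSDWarning(UserWarning):
    """A kernel matrix is indefinite beyond the PSD tolerance."""


def validate_psd(matrix: np.ndarray, tol: float = PSD_TOL) -> tuple[bool, float]:
    """Check positive semidefiniteness of a symmetric matrix.

    Returns ``(is_psd, smallest_eigenvalue)`` where ``is_psd`` is true iff
    the smallest eigenvalue is at least ``-tol * largest_eigenvalue``
    (the largest eigenvalue is taken as 1 for an all-zero matrix).

    Raises
    ------
    DataError
        If the matrix is not square or not symmetric within tolerance.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DataError(f"matrix must be square, got shape {matrix.shape}")
    scale = np.abs(matrix).max() if matrix.size else 0.0
    if scale > 0 and np.abs(matrix - matrix.T).max() > SYMMETRY_TOL * scale:
        raise DataError("matrix is not symmetric within tolerance")
    if tol < 0:
        raise DataError("PSD tolerance must be nonnegative")
    eigvals = np.linalg.eigvalsh((matrix + matrix.T) / 2.0)
    smallest = float(eigvals[0])
    largest = float(eigvals[-1])
    ref = largest if largest > 0 else 1.0
    return smallest >= -tol * ref, smallest


@dataclass
class NodeKernel:
    """A symmetric PSD similarity matrix over named nodes.

    Parameters
    ----------
    node_ids : list of str
        Unique node identifiers; row/column order of ``matrix``.
    matrix : ndarray of shape (m, m)
        Similarity values K(x_i, x_j).
    name : str, optional
        A label for reporting (usually the source file stem).
    strict : bool
        If true, a PSD violation beyond tolerance raises instead of warning.
    """

    node_ids: list[str]
    matrix: np.ndarray
    name: str = "kernel"
    strict: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.node_ids = [str(i) for i in self.node_ids]
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=float))
        m = len(self.node_ids)
        if self.matrix.shape != (m, m):
            raise DataError(
                f"kernel '{self.name}': matrix shape {self.matrix.shape} does not "
                f"match {m} node ids"
            )
        if len(set(self.node_ids)) != m:
            raise DataError(f"kernel '{self.name}': node ids are not unique")
        if not np.isfinite(self.matrix).all():
            raise DataError(f"kernel '{self.name}': non-finite entries")
        ok, smallest = validate_psd(self.matrix)
        if not ok:
            msg = (
                f"kernel '{self.name}' is not PSD within tolerance "
                f"(smallest eigenvalue {smallest:.3e})"
            )
            if self.strict:
                raise DataError(msg)
            warnings.warn(msg, PSDWarning, stacklevel=2)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except AttributeError:
            self._index = {nid: i for i, nid in enumerate(self.node_ids)}
            return self._index[node_id]


def read_node_kernel(path, strict: bool = False, name: str | None = None) -> NodeKernel:
    """Read a node kernel from TSV.

    Format: first cell empty, then the m node IDs; each following row is a
    node ID followed by m floats.  The header row and the leading column
    must list the same IDs in the same order.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                         float_precision="round_trip")
    except Exception as exc:  # malformed file
        raise DataError(f"cannot parse kernel file {path}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise DataError(f"{path}: kernel body is not square ({df.shape[0]}x{df.shape[1]})")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise DataError(f"{path}: header row IDs and leading-column IDs disagree")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise DataError(f"{path}: non-numeric cell in kernel body")
    if name is None:
        name = _stem(path)
    return NodeKernel(node_ids=row_ids, matrix=body.astype(float), name=name, strict=strict)


def write_node_kernel(kernel: NodeKernel, path) -> None:
    """Write a node kernel as TSV, values at 17 significant digits (round-trip exact)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(kernel.node_ids) + "\n")
        for nid, row in zip(kernel.node_ids, kernel.matrix):
            fh.write(nid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def normalize_kernel(kernel: NodeKernel) -> NodeKernel:
    """Cosine-normalize a kernel: K'_ij = K_ij / sqrt(K_ii K_jj).

    Equivalent to mapping every implicit feature vector to unit length,
    which gives heterogeneous data sources a common scale.  The output has
    unit diagonal; off-diagonal entries lie in [-1, 1].

    Raises
    ------
    DataError
        If any diagonal entry is zero or negative (names the offending node).
    """
    diag = np.diag(kernel.matrix)
    bad = np.where(diag <= 0)[0]
    if bad.size:
        raise DataError(
            f"kernel '{kernel.name}': nonpositive diagonal for node "
            f"'{kernel.node_ids[bad[0]]}' (K_ii = {diag[bad[0]]:.6g})"
        )
    inv = 1.0 / np.sqrt(diag)
    out = kernel.matrix * np.outer(inv, inv)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0
    return NodeKernel(node_ids=list(kernel.node_ids), matrix=out, name=kernel.name,
                      strict=kernel.strict)


def align_kernels(kernels: list[NodeKernel]) -> list[NodeKernel]:
    """Align several kernels to the node order of the first.

    Alignment is by string ID.  If any kernel covers a different node *set*
    this is an error — silent intersection would hide data problems.
    """
    if not kernels:
        raise DataError("no kernels to align")
    ref = kernels[0]
    ref_set = set(ref.node_ids)
    aligned = [ref]
    for k in kernels[1:]:
        if set(k.node_ids) != ref_set:
            missing = sorted(ref_set - set(k.node_ids))[:5]
            extra = sorted(set(k.node_ids) - ref_set)[:5]
            raise DataError(
                f"kernel '{k.name}' covers a different node set than "
                f"'{ref.name}' (missing e.g. {missing}, extra e.g. {extra})"
            )
        if k.node_ids == ref.node_ids:
            aligned.append(k)
        else:
            order = [k.index_of(nid) for nid in ref.node_ids]
            aligned.append(
                NodeKernel(node_ids=list(ref.node_ids),
                           matrix=k.matrix[np.ix_(order, order)],
                           name=k.name, strict=k.strict)
            )
    return aligned


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base
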