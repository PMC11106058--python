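"""Data model and vectorization conventions for network-valued regression.

A sample is a symmetric ``V x V`` adjacency matrix ``A_i`` (nonnegative edge
weights; the diagonal carries node presence/value) paired with a scalar
response ``y_i``.  The linear predictor is the Frobenius inner product
``<A_i, B>_F`` with a symmetric coefficient matrix ``B``, which is equivalent
to an ordinary regression ``x_i . gamma`` on the vectorized upper triangle:
off-diagonal coefficients satisfy ``b_kl = gamma_kl / 2`` (each unordered pair
appears twice in the Frobenius sum) while diagonal coefficients are carried
unhalved (``b_kk = gamma_kk``).

The column ordering of the upper triangle is row-major -- ``(0,0), (0,1), ...,
(0,V-1), (1,1), ...`` -- i.e. exactly ``numpy.triu_indices``.  Everything
downstream (sampler, simulators, file formats) shares this one convention via
:class:`IndexMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYMMETRY_TOL = 1e-10


class IndexMap:
    """Bijection between upper-triangle positions ``(k, l)`` and flat columns.

    Parameters
    ----------
    V : int
        Number of nodes.
    include_diagonal : bool
        When True (default) the diagonal (node main effects) is part of the
        vectorization and ``q = V(V+1)/2``; when False only the ``V(V-1)/2``
        strict upper-triangle entries are kept.
    """

    def __init__(self, V: int, include_diagonal: bool = True):
        if V < 1:
            raise ValueError(f"V must be a positive integer, got {V}")
        self.V = int(V)
        self.include_diagonal = bool(include_diagonal)
        offset = 0 if include_diagonal else 1
        self.rows, self.cols = np.triu_indices(self.V, k=offset)
        self.q = self.rows.size
        self._column = np.full((self.V, self.V), -1, dtype=np.int64)
        self._column[self.rows, self.cols] = np.arange(self.q)
        self._column[self.cols, self.rows] = np.arange(self.q)

    def column_of(self, k: int, l: int) -> int:
        """Flat column index of the (unordered) pair ``(k, l)``."""
        j = self._column[k, l]
        if j < 0:
            raise KeyError(f"pair ({k}, {l}) is not mapped (diagonal excluded)")
        return int(j)

    def pair_of(self, j: int) -> tuple[int, int]:
        return int(self.rows[j]), int(self.cols[j])

    @property
    def diagonal_columns(self) -> np.ndarray:
        """Columns holding node main effects (empty if diagonal excluded)."""
        return np.flatnonzero(self.rows == self.cols)

    @property
    def offdiagonal_columns(self) -> np.ndarray:
        return np.flatnonzero(self.rows != self.cols)

    def incident_columns(self, k: int) -> np.ndarray:
        """Columns of the ``V - 1`` off-diagonal entries touching node ``k``.

        Ordered by the other endpoint ascending, matching the conventional
        ordering of the per-node scale matrix ``H_k = diag(s_1k, ...,
        s_{k-1,k}, s_{k,k+1}, ..., s_kV)``.
        """
        others = np.delete(np.arange(self.V), k)
        return self._column[k, others]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IndexMap)
            and other.V == self.V
            and other.include_diagonal == self.include_diagonal
        )

    def __repr__(self) -> str:
        return f"IndexMap(V={self.V}, q={self.q}, include_diagonal={self.include_diagonal})"


def build_index_map(V: int, include_diagonal: bool = True) -> IndexMap:
    """Construct the row-major upper-triangle index map for ``V`` nodes."""
    return IndexMap(V, include_diagonal=include_diagonal)


def _check_symmetric(A: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency matrix contains non-finite entries")
    if np.max(np.abs(A - A.T), initial=0.0) > tol:
        raise ValueError(f"matrix is asymmetric beyond tolerance {tol}")
    # symmetrize exactly so downstream code can rely on A == A.T
    return (A + A.T) / 2.0


def vectorize_adjacency(A: np.ndarray, index_map: IndexMap) -> np.ndarray:
    """Upper triangle (including the diagonal when mapped) of ``A`` as a vector."""
    A = _check_symmetric(A)
    if A.shape[0] != index_map.V:
        raise ValueError(f"matrix has {A.shape[0]} nodes, index map expects {index_map.V}")
    return A[index_map.rows, index_map.cols].copy()


def devectorize(x: np.ndarray, index_map: IndexMap) -> np.ndarray:
    """Inverse of :func:`vectorize_adjacency` (unmapped entries are zero)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (index_map.q,):
        raise ValueError(f"expected a length-{index_map.q} vector, got shape {x.shape}")
    A = np.zeros((index_map.V, index_map.V))
    A[index_map.rows, index_map.cols] = x
    A[index_map.cols, index_map.rows] = x
    return A


def gamma_to_B(gamma: np.ndarray, index_map: IndexMap) -> np.ndarray:
    """Coefficient matrix ``B`` from the vectorized coefficients ``gamma``.

    Off-diagonal ``b_kl = gamma_kl / 2``; diagonal ``b_kk = gamma_kk``, so
    that ``<A, B>_F == vectorize(A) . gamma`` exactly.
    """
    B = devectorize(gamma, index_map)
    off = index_map.rows != index_map.cols
    r, c = index_map.rows[off], index_map.cols[off]
    B[r, c] /= 2.0
    B[c, r] = B[r, c]
    return B


def B_to_gamma(B: np.ndarray, index_map: IndexMap) -> np.ndarray:
    """Inverse of :func:`gamma_to_B`: ``gamma_kl = 2 b_kl`` off-diagonal."""
    gamma = vectorize_adjacency(B, index_map)
    gamma[index_map.rows != index_map.cols] *= 2.0
    return gamma


def compute_W(u: np.ndarray, lam: np.ndarray, index_map: IndexMap) -> np.ndarray:
    """Prior-mean vector ``W`` with ``W_kl = u_k^T diag(lam) u_l`` for k <= l."""
    u = np.asarray(u, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if u.ndim != 2 or u.shape[0] != index_map.V:
        raise ValueError(f"u must be ({index_map.V}, R), got shape {u.shape}")
    if lam.shape != (u.shape[1],):
        raise ValueError(f"lambda must have length R={u.shape[1]}, got shape {lam.shape}")
    G = (u * lam) @ u.T
    return G[index_map.rows, index_map.cols]


@dataclass
class NetworkDataset:
    """A sample of microbial networks with a continuous phenotype.

    ``adjacency`` holds one symmetric nonnegative ``V x V`` matrix per sample
    (stored stacked as ``(n, V, V)``), ``response`` the phenotype vector, and
    ``taxa`` the shared node labels (the union of nodes over all samples; a
    node absent from a sample simply has zero rows/columns).
    """

    adjacency: np.ndarray
    response: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        mats = [_check_symmetric(A) for A in self.adjacency]
        if not mats:
            raise ValueError("dataset must contain at least one sample")
        V = mats[0].shape[0]
        for i, A in enumerate(mats):
            if A.shape[0] != V:
                raise ValueError(
                    f"sample {i} has {A.shape[0]} nodes but sample 0 has {V}; "
                    "all samples must share the same node set and ordering"
                )
        self.adjacency = np.stack(mats)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.ndim != 1 or self.response.size != len(mats):
            raise ValueError(
                f"response must be a length-{len(mats)} vector, got shape {self.response.shape}"
            )
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response contains non-finite values")
        if not self.taxa:
            self.taxa = [f"t{i+1}" for i in range(V)]
        if len(self.taxa) != V:
            raise ValueError(f"{len(self.taxa)} taxon labels for {V} nodes")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def V(self) -> int:
        return self.adjacency.shape[1]


@dataclass
class DesignMatrix:
    """``n x q`` model matrix of vectorized upper triangles plus its index map."""

    X: np.ndarray
    index_map: IndexMap

    @property
    def V(self) -> int:
        return self.index_map.V

    @property
    def q(self) -> int:
        return self.index_map.q


def build_design_matrix(dataset: NetworkDataset, include_diagonal: bool = True) -> DesignMatrix:
    """Stack the vectorized adjacency matrices of ``dataset`` into a model matrix."""
    imap = build_index_map(dataset.V, include_diagonal=include_diagonal)
    X = dataset.adjacency[:, imap.rows, imap.cols]
    return DesignMatrix(X=np.ascontiguousarray(X), index_map=imap)


@dataclass
class Hyperparameters:
    """Prior hyperparameters of the network-regression model.

    R : latent dimension of the per-node factors ``u_k``.
    eta : Dirichlet tilt (> 1) biasing higher latent components toward zero.
    nu : inverse-Wishart degrees of freedom for the slab covariance ``M``
        (must exceed ``R - 1``; defaults to ``R + 2`` so the prior mean exists).
    a_delta, b_delta : Beta shape parameters of the node-inclusion rate.
    zeta, iota : Gamma shape/rate of the scale hyperparameter ``theta``.
    """

    R: int = 5
    eta: float = 1.01
    nu: float | None = None
    a_delta: float = 1.0
    b_delta: float = 1.0
    zeta: float = 1.0
    iota: float = 1.0

    def __post_init__(self):
        if self.R < 1:
            raise ValueError(f"R must be a positive integer, got {self.R}")
        if self.nu is None:
            self.nu = float(self.R + 2)
        if self.eta <= 1.0:
            raise ValueError(f"eta must exceed 1, got {self.eta}")
        if self.nu <= self.R - 1:
            raise ValueError(f"nu must exceed R - 1 = {self.R - 1}, got {self.nu}")
        for name in ("a_delta", "b_delta", "zeta", "iota"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
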