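"""Regional LD structure and the eigen-space quantities the likelihood uses.

A region's linkage-disequilibrium (LD) correlation matrix ``R`` enters the
Z-score likelihood both directly (sampling correlation between marginal
test statistics) and through the LD score matrix ``L = R @ R``, whose
diagonal entries are the classical per-variant LD scores
``l_j = sum_k R_jk**2``.  Because ``L`` is the matrix square of ``R``, both
matrices share the eigenvectors of ``R``: if ``R = U diag(lam) U^T`` then
``L = U diag(lam**2) U^T``.  Every covariance matrix the model builds is a
linear combination of ``R`` and ``L`` and is therefore diagonalized by
``U`` — the 2M-dimensional Gaussian likelihood reduces to K independent
2x2 problems.  :class:`LDBlock` precomputes and stores that eigen-structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LDBlock",
    "build_ld_block",
    "simulate_ld_ar1",
    "simulate_ld_blocks",
    "read_ld_text",
    "read_ld_binary",
]

#: default relative eigenvalue cutoff (fraction of the largest eigenvalue)
DEFAULT_RELATIVE_TRUNC = 1e-8


@dataclass
class LDBlock:
    """Eigen-decomposed LD correlation matrix for one genomic region.

    Attributes
    ----------
    variant_ids : list of str
        Variant identifiers, in matrix order.
    R : ndarray, shape (M, M)
        Symmetric LD correlation matrix with unit diagonal.
    L : ndarray, shape (M, M)
        LD score matrix, the matrix product ``R @ R``.
    eigvals : ndarray, shape (K,)
        Retained eigenvalues of ``R``, descending, all above ``trunc_tol``.
    eigvecs : ndarray, shape (M, K)
        Orthonormal eigenvectors matching ``eigvals``.
    trunc_tol : float
        Absolute eigenvalue truncation threshold that was applied.
    """

    variant_ids: list[str]
    R: np.ndarray
    L: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    trunc_tol: float
    _sqrt_factor: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def M(self) -> int:
        """Number of variants in the region."""
        return len(self.variant_ids)

    @property
    def K(self) -> int:
        """Number of retained eigen-directions (K <= M)."""
        return self.eigvals.shape[0]

    @property
    def ld_scores(self) -> np.ndarray:
        """Classical per-variant LD scores, ``diag(L)``."""
        return np.diag(self.L).copy()

    def sqrt_factor(self) -> np.ndarray:
        """An M x K factor F with ``F @ F.T = R`` (up to truncation).

        Used by the simulators to draw correlated genotype rows or
        summary-statistic noise; cached after the first call.
        """
        if self._sqrt_factor is None:
            self._sqrt_factor = self.eigvecs * np.sqrt(self.eigvals)
        return self._sqrt_factor

    def project(self, z: np.ndarray) -> np.ndarray:
        """Rotate a length-M vector into the retained eigen-basis (U^T z)."""
        z = np.asarray(z, dtype=float)
        if z.shape != (self.M,):
            raise ValueError(f"expected length-{self.M} vector, got shape {z.shape}")
        return self.eigvecs.T @ z


def build_ld_block(
    R_raw: np.ndarray,
    variant_ids: Sequence[str] | None = None,
    trunc_tol: float | None = None,
) -> LDBlock:
    """Validate, symmetrize and eigen-decompose a raw LD correlation matrix.

    Parameters
    ----------
    R_raw : array-like, shape (M, M)
        Correlation matrix; small asymmetries and diagonal drift from
        reference-panel estimation are repaired (symmetrized, diagonal
        forced to exactly 1).
    variant_ids : sequence of str, optional
        One identifier per variant; synthesized (``v0001`` ...) if omitted.
    trunc_tol : float, optional
        Absolute eigenvalue cutoff; eigenvalues ``<= trunc_tol`` are
        discarded together with their eigenvectors.  Default is
        ``1e-8 * largest eigenvalue``, which removes numerically null
        directions without materially changing the likelihood.

    Raises
    ------
    ValueError
        On non-square input, dimension mismatch with ``variant_ids``,
        non-finite entries, entries far outside [-1, 1], or when every
        eigenvalue falls below the cutoff (degenerate region).
    """
    R = np.array(R_raw, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"LD matrix must be square, got shape {R.shape}")
    M = R.shape[0]
    if M < 2:
        raise ValueError("LD block needs at least 2 variants")
    if variant_ids is None:
        width = len(str(M))
        variant_ids = [f"v{i + 1:0{width}d}" for i in range(M)]
    variant_ids = [str(v) for v in variant_ids]
    if len(variant_ids) != M:
        raise ValueError(
            f"variant_ids length {len(variant_ids)} != matrix dimension {M}"
        )
    if len(set(variant_ids)) != M:
        raise ValueError("variant_ids contain duplicates")
    if not np.all(np.isfinite(R)):
        raise ValueError("LD matrix contains non-finite entries")
    if np.any(np.abs(R) > 1.0 + 1e-8):
        raise ValueError("LD matrix entries outside [-1, 1]")

    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)

    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if trunc_tol is None:
        trunc_tol = DEFAULT_RELATIVE_TRUNC * float(eigvals[0])
    if trunc_tol < 0:
        raise ValueError("trunc_tol must be >= 0")
    keep = eigvals > trunc_tol
    if not np.any(keep):
        raise ValueError("degenerate region: all eigenvalues below trunc_tol")

    return LDBlock(
        variant_ids=variant_ids,
        R=R,
        L=R @ R,
        eigvals=np.ascontiguousarray(eigvals[keep]),
        eigvecs=np.ascontiguousarray(eigvecs[:, keep]),
        trunc_tol=float(trunc_tol),
    )


def simulate_ld_ar1(
    M: int, rho: float, variant_prefix: str = "snp", trunc_tol: float | None = None
) -> LDBlock:
    """AR(1) LD block: ``R_ij = rho ** |i - j|``.

    A standard stand-in for the decaying LD of a real cis region;
    positive definite for any ``|rho| < 1`` and deterministic.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("AR(1) rho must satisfy |rho| < 1")
    if M < 2:
        raise ValueError("M must be >= 2")
    idx = np.arange(M)
    R = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = [f"{variant_prefix}{i + 1}" for i in range(M)]
    return build_ld_block(R, ids, trunc_tol=trunc_tol)


def simulate_ld_blocks(
    M: int,
    n_blocks: int,
    within_rho: float,
    seed: int | None = None,
    variant_prefix: str = "snp",
    jitter: float = 0.0,
) -> LDBlock:
    """Block-diagonal compound-symmetry LD.

    Variants are split into ``n_blocks`` contiguous groups (the last group
    absorbs any remainder); correlation is ``within_rho`` inside a group
    and 0 across groups.  With ``jitter > 0`` a small seed-controlled
    symmetric perturbation is added inside blocks (diagonal restored),
    emulating reference-panel sampling noise.
    """
    if not 0.0 <= within_rho < 1.0:
        raise ValueError("within_rho must be in [0, 1)")
    if M < 2 or n_blocks < 1 or n_blocks > M:
        raise ValueError("need 2 <= M and 1 <= n_blocks <= M")
    size = M // n_blocks
    R = np.zeros((M, M))
    starts = [i * size for i in range(n_blocks)]
    ends = starts[1:] + [M]
    for s, e in zip(starts, ends):
        b = e - s
        R[s:e, s:e] = within_rho * np.ones((b, b)) + (1 - within_rho) * np.eye(b)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter, size=(M, M))
        noise = 0.5 * (noise + noise.T)
        for s, e in zip(starts, ends):
            R[s:e, s:e] += noise[s:e, s:e]
        R = np.clip(R, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
    ids = [f"{variant_prefix}{i + 1}" for i in range(M)]
    return build_ld_block(R, ids)


def read_ld_text(
    path: str | Path,
    variant_ids: Sequence[str] | None = None,
    trunc_tol: float | None = None,
) -> LDBlock:
    """Read a dense square LD matrix from delimited text.

    Whitespace- and comma-delimited layouts are both accepted.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    R = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return build_ld_block(R, variant_ids, trunc_tol=trunc_tol)


def read_ld_binary(
    path: str | Path,
    snplist_path: str | Path,
    trunc_tol: float | None = None,
) -> LDBlock:
    """Read a raw float64 square LD matrix with a sidecar variant list.

    ``snplist_path`` holds one variant identifier per line, in matrix
    order; the matrix dimension is inferred from the list length and
    checked against the file size.
    """
    ids = [
        line.strip()
        for line in Path(snplist_path).read_text().splitlines()
        if line.strip()
    ]
    M = len(ids)
    flat = np.fromfile(path, dtype=np.float64)
    if flat.size != M * M:
        raise ValueError(
            f"binary LD file holds {flat.size} float64 values, expected {M * M} "
            f"for the {M} variants in {snplist_path}"
        )
    return build_ld_block(flat.reshape(M, M), ids, trunc_tol=trunc_tol)
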