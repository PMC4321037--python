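"""Covariance kernels for genomic prediction on the liability scale.

Builds the genomic relationship matrix G = ZZ'/p from centered, standardized
marker scores, the additive x additive epistasis kernel GA = G # G (Hadamard
square), record-level incidence matrices, and the record-level interaction
kernels (Zg K Zg') # (ZE ZE') that give marker effects an environment-specific
component (reaction-norm G x E).

All kernels are symmetric and positive semi-definite up to numerical jitter;
record-level interaction kernels are materialized per environment (they are
block-diagonal once records are sorted by environment), with a dense Hadamard
reference construction retained for cross-checking.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .data_io import PhenotypeTable, RawGenotypes

logger = logging.getLogger("tgblup")

#: relative eigenvalue cutoff below which kernel components are treated as null
EIGEN_REL_TOL = 1e-10
#: diagonal jitter (relative to mean diagonal) used when a factorization fails
PSD_JITTER = 1e-8

__all__ = [
    "MarkerMatrix",
    "Kernel",
    "IncidenceSet",
    "EigenSummary",
    "standardize_markers",
    "compute_grm",
    "epistasis_kernel",
    "identity_kernel",
    "build_incidence",
    "interaction_kernel",
    "eigen_summary",
    "kernel_factor",
]


@dataclasses.dataclass
class MarkerMatrix:
    """Post-QC marker data: counts X, frequencies p, standardized scores Z.

    z_jm = (x_jm - 2 p_m) / sqrt(2 p_m (1 - p_m)); columns of Z have zero
    mean when p_m is the sample frequency, which makes sigma_g^2 of the GRM
    interpretable as a genomic variance.
    """

    X: np.ndarray
    p: np.ndarray
    Z: np.ndarray
    line_ids: tuple
    marker_ids: tuple

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclasses.dataclass
class Kernel:
    """A named symmetric PSD covariance matrix over lines or records."""

    name: str
    matrix: np.ndarray
    level: str  # "line" | "record"
    ids: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = self.matrix
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError(f"kernel {self.name!r} is not square: {k.shape}")
        scale = max(1.0, float(np.abs(k).max(initial=0.0)))
        if not np.allclose(k, k.T, atol=1e-10 * scale):
            raise ValueError(f"kernel {self.name!r} is not symmetric")
        if self.level not in ("line", "record"):
            raise ValueError(f"kernel level must be 'line' or 'record', got {self.level!r}")
        if len(self.ids) != k.shape[0]:
            raise ValueError(f"kernel {self.name!r}: {len(self.ids)} ids for {k.shape[0]} rows")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def mean_diagonal(self) -> float:
        return float(np.mean(np.diag(self.matrix)))


@dataclasses.dataclass
class IncidenceSet:
    """Record-level incidence structure connecting records to lines/environments.

    Dense 0/1 matrices (Zg, ZE, and their aliases X_E for the fixed-effect
    design and Z_L for the line term) are built on demand from the integer
    code arrays; every row has exactly one unit entry.
    """

    env_ids: tuple
    line_ids: tuple
    env_codes: np.ndarray
    line_codes: np.ndarray

    def __post_init__(self) -> None:
        self.env_codes = np.asarray(self.env_codes, dtype=int)
        self.line_codes = np.asarray(self.line_codes, dtype=int)
        if self.env_codes.shape != self.line_codes.shape:
            raise ValueError("env/line code arrays differ in length")

    @property
    def n_records(self) -> int:
        return len(self.env_codes)

    @property
    def Zg(self) -> np.ndarray:
        return np.eye(len(self.line_ids))[self.line_codes]

    @property
    def ZE(self) -> np.ndarray:
        return np.eye(len(self.env_ids))[self.env_codes]

    @property
    def X_E(self) -> np.ndarray:
        return self.ZE

    @property
    def Z_L(self) -> np.ndarray:
        return self.Zg


@dataclasses.dataclass
class EigenSummary:
    """Descending eigenvalues of a kernel and how many explain a variance share."""

    eigenvalues: np.ndarray
    n_components: int
    proportions: np.ndarray


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def standardize_markers(geno: RawGenotypes) -> MarkerMatrix:
    """Center and standardize post-QC genotype calls.

    Requires no missing calls and no monomorphic markers (both guaranteed
    after :func:`tgblup.data_io.qc_markers`).
    """
    X = np.asarray(geno.calls, dtype=float)
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing calls; run qc_markers first")
    p = X.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = [m for m, pm in zip(geno.marker_ids, p) if pm <= 0.0 or pm >= 1.0]
        raise ValueError(f"monomorphic markers cannot be standardized: {bad[:5]}")
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return MarkerMatrix(X, p, Z, tuple(geno.line_ids), tuple(geno.marker_ids))


def compute_grm(markers: MarkerMatrix) -> Kernel:
    """Genomic relationship matrix G = ZZ'/p over lines (no further rescaling)."""
    if markers.n_markers < 1:
        raise ValueError("at least one marker is required")
    G = markers.Z @ markers.Z.T / markers.n_markers
    return Kernel("G", G, "line", markers.line_ids)


def epistasis_kernel(G: Kernel) -> Kernel:
    """Additive x additive epistasis kernel GA = G # G (elementwise square).

    PSD is preserved by the Schur product theorem.
    """
    if G.level != "line":
        raise ValueError("epistasis kernel requires a line-level G")
    return Kernel("GA", G.matrix * G.matrix, "line", G.ids)


def identity_kernel(ids: Sequence, name: str = "L") -> Kernel:
    """IID line-effect kernel (identity covariance)."""
    ids = tuple(ids)
    return Kernel(name, np.eye(len(ids)), "line", ids)


def build_incidence(pheno: PhenotypeTable, line_ids: Optional[Sequence] = None) -> IncidenceSet:
    """Incidence structure for a phenotype table.

    ``line_ids`` fixes the line order (normally the genotyped/kernel lines);
    phenotyped lines absent from it raise an error listing the ids.
    """
    if pheno.n_records == 0:
        raise ValueError("phenotype table has no records")
    if line_ids is None:
        line_ids = pheno.line_ids
    line_ids = tuple(line_ids)
    pos = {l: j for j, l in enumerate(line_ids)}
    missing = [l for l in pheno.line_ids if l not in pos]
    if missing:
        raise ValueError(f"phenotyped lines absent from genotypes: {missing}")
    line_codes = pheno.records["line"].map(pos).to_numpy(dtype=int)
    return IncidenceSet(pheno.env_ids, line_ids, pheno.env_index.copy(), line_codes)


def interaction_kernel(kernel: Kernel, inc: IncidenceSet, method: str = "block") -> Kernel:
    """Record-level interaction kernel (Zg K Zg') # (ZE ZE').

    Entry (r, s) equals K[line_r, line_s] when records r and s share an
    environment and 0 otherwise; the default per-environment block
    construction and the dense Hadamard product (``method="dense"``) are
    contract-equal.
    """
    if kernel.level != "line":
        raise ValueError("interaction kernel requires a line-level kernel")
    n = inc.n_records
    if method == "dense":
        Zg, ZE = inc.Zg, inc.ZE
        K = (Zg @ kernel.matrix @ Zg.T) * (ZE @ ZE.T)
    elif method == "block":
        K = np.zeros((n, n))
        for i in range(len(inc.env_ids)):
            rows = np.flatnonzero(inc.env_codes == i)
            lines = inc.line_codes[rows]
            K[np.ix_(rows, rows)] = kernel.matrix[np.ix_(lines, lines)]
    else:
        raise ValueError(f"unknown method {method!r}")
    return Kernel(f"{kernel.name}xE", K, "record", tuple(range(n)))


# ---------------------------------------------------------------------------
# spectral utilities
# ---------------------------------------------------------------------------

def eigen_summary(K: Kernel, variance_threshold: float = 0.80) -> EigenSummary:
    """Eigenvalues of a kernel and the number of components reaching a
    cumulative variance threshold (negatives below jitter tolerance are
    clipped to zero before proportions are formed)."""
    lam = np.linalg.eigvalsh(K.matrix)[::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0.0:
        raise ValueError("kernel has nonpositive trace; no variance to summarize")
    proportions = lam / total
    cumulative = np.cumsum(proportions)
    n_components = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    return EigenSummary(lam, n_components, proportions)


def kernel_factor(K: Kernel, rel_tol: float = EIGEN_REL_TOL) -> np.ndarray:
    """Factor F (J x r) with K ~= F F', from the eigendecomposition of K.

    Eigenvalues below ``rel_tol`` times the largest are dropped, constraining
    effects drawn with this factor to the kernel's column space.  If the
    eigensolver fails, a diagonal jitter of PSD_JITTER * mean(diag) is added
    once and the decomposition retried.
    """
    try:
        lam, U = np.linalg.eigh(K.matrix)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical rescue path
        jitter = PSD_JITTER * max(K.mean_diagonal(), 1.0)
        logger.warning("eigendecomposition of %s failed; retrying with jitter %.1e", K.name, jitter)
        lam, U = np.linalg.eigh(K.matrix + jitter * np.eye(K.size))
    lam_max = float(lam.max(initial=0.0))
    if lam_max <= 0.0:
        raise ValueError(f"kernel {K.name!r} has no positive eigenvalues")
    keep = lam > rel_tol * lam_max
    return U[:, keep] * np.sqrt(lam[keep])
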