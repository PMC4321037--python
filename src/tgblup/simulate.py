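"""Synthetic genotypes and ordinal phenotypes under the threshold model.

Generates biallelic SNP genotypes (binomial draws at per-marker allele
frequencies), kernel-structured random effects, liabilities, and ordinal
scores under any combination of the effect blocks, so every stage of the
pipeline is testable without external data.  Effects are drawn via the same
kernel eigen-factorization the sampler uses, so simulation and inference
share one covariance convention.

:func:`study_shaped_fixture` produces a desk-scale synthetic stand-in for
the multi-environment maize gray-leaf-spot layout: three environments,
five ordinal categories, unequal replication with environment totals ordered
like the study's (echoing 1485/832/481), and a liability variance dominated
by the G x E component.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data_io import PhenotypeTable, RawGenotypes
from .kernels import compute_grm, epistasis_kernel, kernel_factor, standardize_markers
from .sampler import BLOCK_ORDER, PER_ENV_BLOCKS

logger = logging.getLogger("tgblup")

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_dataset",
    "study_shaped_fixture",
]


@dataclasses.dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated multi-environment ordinal trait.

    ``variances`` maps effect-block names (subset of L, G, GxG, GxE, GxGxE)
    to true liability-scale variance components; blocks with zero variance
    may simply be omitted.  ``replicates`` is either a fixed count per
    (environment, line) cell or an inclusive (low, high) range sampled
    uniformly, mimicking unequal N_ij.
    """

    n_lines: int
    n_envs: int
    n_markers: int
    categories: int
    beta: Sequence[float]
    variances: Dict[str, float]
    thresholds: Sequence[float]
    replicates: Union[int, Tuple[int, int]] = (1, 6)
    allele_frequency_range: Tuple[float, float] = (0.1, 0.9)
    error_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.beta) != self.n_envs:
            raise ValueError("one true fixed effect per environment is required")
        if len(self.thresholds) != self.categories - 1:
            raise ValueError("C - 1 finite thresholds are required")
        if self.thresholds[0] != 0.0 or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing with gamma_1 = 0")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("true variances must be nonnegative")
        if self.error_variance < 0:
            raise ValueError("error variance must be nonnegative")
        unknown = set(self.variances) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown effect blocks {sorted(unknown)}")
        lo, hi = self.allele_frequency_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequency range must lie inside (0, 1)")


@dataclasses.dataclass
class SyntheticTruth:
    """Realized effects and liabilities behind a simulated data set."""

    effects: Dict[str, np.ndarray]   # block -> (J,) or (I, J)
    liabilities: np.ndarray
    config: SimulationConfig

    def dominant_block(self) -> str:
        return max(self.config.variances, key=self.config.variances.get)


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    frequency_range: Tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> RawGenotypes:
    """Biallelic SNP genotypes: per-marker frequency uniform in the range,
    calls binomial(2, freq) per line (Hardy-Weinberg draws, no missingness)."""
    if n_lines < 1 or n_markers < 1:
        raise ValueError("n_lines and n_markers must be positive")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*frequency_range, size=n_markers)
    calls = rng.binomial(2, freqs, size=(n_lines, n_markers)).astype(float)
    line_ids = tuple(f"L{j + 1:04d}" for j in range(n_lines))
    marker_ids = tuple(f"M{m + 1:05d}" for m in range(n_markers))
    return RawGenotypes(line_ids, marker_ids, calls)


def _line_factors(geno: RawGenotypes, blocks) -> Dict[str, np.ndarray]:
    """Kernel factors (K = F F') backing the requested effect blocks.

    Monomorphic markers (possible by chance at small J) are dropped before
    standardization.
    """
    factors: Dict[str, np.ndarray] = {}
    marker_blocks = {"G", "GxG", "GxE", "GxGxE"} & set(blocks)
    if marker_blocks:
        calls = geno.calls
        p = calls.mean(axis=0) / 2.0
        poly = (p > 0.0) & (p < 1.0)
        if not poly.all():
            logger.info("dropping %d monomorphic simulated markers", int((~poly).sum()))
            geno = RawGenotypes(
                geno.line_ids,
                tuple(m for m, keep in zip(geno.marker_ids, poly) if keep),
                calls[:, poly],
            )
        G = compute_grm(standardize_markers(geno))
        f_g = kernel_factor(G)
        for name in marker_blocks & {"G", "GxE"}:
            factors[name] = f_g
        if marker_blocks & {"GxG", "GxGxE"}:
            f_ga = kernel_factor(epistasis_kernel(G))
            for name in marker_blocks & {"GxG", "GxGxE"}:
                factors[name] = f_ga
    if "L" in blocks:
        factors["L"] = np.eye(geno.n_lines)
    return factors


def _simulate(
    config: SimulationConfig, geno: RawGenotypes, reps: np.ndarray, rng: np.random.Generator
) -> Tuple[PhenotypeTable, SyntheticTruth]:
    """Core generator given an explicit (I, J) replication matrix."""
    blocks = [b for b in BLOCK_ORDER if config.variances.get(b, 0.0) > 0.0]
    factors = _line_factors(geno, blocks)
    J, I = config.n_lines, config.n_envs

    effects: Dict[str, np.ndarray] = {}
    for name in blocks:
        f = factors[name]
        sd = np.sqrt(config.variances[name])
        if name in PER_ENV_BLOCKS:
            effects[name] = np.stack(
                [sd * (f @ rng.standard_normal(f.shape[1])) for _ in range(I)]
            )
        else:
            effects[name] = sd * (f @ rng.standard_normal(f.shape[1]))

    env_col, line_col, rep_col, env_idx, line_idx = [], [], [], [], []
    for i in range(I):
        for j in range(J):
            for k in range(reps[i, j]):
                env_col.append(f"E{i + 1}")
                line_col.append(geno.line_ids[j])
                rep_col.append(k + 1)
                env_idx.append(i)
                line_idx.append(j)
    env_idx = np.asarray(env_idx, dtype=int)
    line_idx = np.asarray(line_idx, dtype=int)
    if len(env_idx) == 0:
        raise ValueError("replication layout produced no records")

    liab = config.beta[env_idx] + np.sqrt(config.error_variance) * rng.standard_normal(len(env_idx))
    for name in blocks:
        eff = effects[name]
        liab += eff[env_idx, line_idx] if eff.ndim == 2 else eff[line_idx]
    score = np.searchsorted(config.thresholds, liab) + 1

    records = pd.DataFrame(
        {"env": env_col, "line": line_col, "rep": rep_col, "score": score.astype(int)}
    )
    pheno = PhenotypeTable(records, config.categories)
    return pheno, SyntheticTruth(effects, liab, config)


def simulate_dataset(
    config: SimulationConfig, geno: RawGenotypes
) -> Tuple[PhenotypeTable, SyntheticTruth]:
    """Simulate ordinal phenotypes for the given genotypes.

    Per included block, line-level effects are drawn from N(0, K sigma^2)
    via the kernel factorization (independently per environment for the
    interaction blocks); liability = E_i + block contributions + N(0,
    error_variance) noise (unit variance by default, matching the fitted
    model), and the observed category is the threshold interval containing
    the liability.  Output is a pure function of ``config`` (incl. its seed)
    and the genotypes.
    """
    if geno.n_lines != config.n_lines:
        raise ValueError(
            f"genotypes have {geno.n_lines} lines but config expects {config.n_lines}"
        )
    rng = np.random.default_rng(config.seed)
    if isinstance(config.replicates, int):
        reps = np.full((config.n_envs, config.n_lines), config.replicates, dtype=int)
    else:
        lo, hi = config.replicates
        reps = rng.integers(lo, hi + 1, size=(config.n_envs, config.n_lines))
    return _simulate(config, geno, reps, rng)


def study_shaped_fixture(seed: int = 0) -> Tuple[PhenotypeTable, RawGenotypes]:
    """Desk-scale synthetic stand-in for the study's multi-environment layout.

    Three environments with five ordinal categories; per-line replication is
    heaviest in environment 1 and lightest in environment 3 so environment
    record totals are strictly ordered (proportions echoing 1485/832/481);
    60 lines x 300 markers with a G x E-dominated liability variance.
    """
    rng = np.random.default_rng(seed)
    J, p, I, C = 60, 300, 3, 5
    geno = simulate_genotypes(J, p, (0.1, 0.9), seed=int(rng.integers(2**31)))
    config = SimulationConfig(
        n_lines=J,
        n_envs=I,
        n_markers=p,
        categories=C,
        beta=(1.0, 1.2, 1.5),
        variances={"L": 0.05, "G": 0.2, "GxE": 1.0},
        thresholds=(0.0, 0.8, 1.6, 2.4),
        seed=seed,
    )
    # env-graded replication mimicking the study's unequal totals
    reps = np.stack(
        [
            rng.integers(3, 5, size=J),
            rng.integers(1, 4, size=J),
            rng.integers(0, 3, size=J),
        ]
    )
    # enforce strictly ordered environment totals (vanishingly rare fix-up)
    while reps[0].sum() <= reps[1].sum():
        reps[0, rng.integers(J)] += 1
    while reps[1].sum() <= reps[2].sum():
        reps[1, rng.integers(J)] += 1

    pheno, _ = _simulate(config, geno, reps, rng)
    return pheno, geno
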