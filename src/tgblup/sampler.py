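"""Threshold GBLUP: nine model variants fitted by Gibbs sampling on liabilities.

The ordinal score y_ijk (environment i, line j, replicate k) is modeled
through a latent liability l_ijk = E_i + sum of random effects + e_ijk with
e_ijk ~ N(0, 1); the category is determined by which threshold interval
(gamma_{c-1}, gamma_c) the liability falls into.  The residual variance is
fixed at 1 and gamma_1 at 0 for identifiability.  The nine specifications
combine six effect blocks:

====== ==========================================================
block  meaning / covariance
====== ==========================================================
E      fixed environment effects (flat Gaussian prior, var 1e10)
L      IID line effects, N(0, I sigma_L^2)
G      genomic line effects, N(0, G sigma_g^2) with G = ZZ'/p
GxG    additive x additive epistasis, N(0, GA sigma_Ag^2), GA = G#G
GxE    reaction-norm interaction, N(0, (Zg G Zg') # (ZE ZE') sigma_gE^2)
GxGxE  epistasis x environment, same with GA
====== ==========================================================

The sampler augments the chain with truncated-normal liabilities
(Albert-Chib data augmentation), draws the free thresholds from their
uniform full conditionals, fixed and random effects from Gaussian full
conditionals, and variance components from scaled-inverse-chi-square full
conditionals.  Random effects are parameterized in the eigenbasis of their
kernel (b = F u with K = F F'), which avoids explicit kernel inverses and is
exact for PSD kernels; interaction blocks exploit the per-environment block
structure so each environment's coefficients are updated independently.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .data_io import PhenotypeTable, RawGenotypes, qc_markers
from .kernels import (
    IncidenceSet,
    Kernel,
    build_incidence,
    compute_grm,
    epistasis_kernel,
    identity_kernel,
    kernel_factor,
    standardize_markers,
)

logger = logging.getLogger("tgblup")

# --- defaults -------------------------------------------------------------
DEFAULT_FIXED_PRIOR_VARIANCE = 1e10
DEFAULT_DF = 5.0
DEFAULT_ITERATIONS = 30_000
DEFAULT_BURNIN = 10_000
DEFAULT_THIN = 5
_VAR_FLOOR = 1e-12

#: effect blocks of each model variant (E is the fixed environment block)
MODEL_BLOCKS: Dict[int, tuple] = {
    1: ("E", "L"),
    2: ("E", "G"),
    3: ("E", "G", "GxG"),
    4: ("E", "L", "G"),
    5: ("E", "L", "G", "GxG"),
    6: ("E", "G", "GxE"),
    7: ("E", "G", "GxG", "GxE", "GxGxE"),
    8: ("E", "L", "G", "GxE"),
    9: ("E", "L", "G", "GxG", "GxE", "GxGxE"),
}

#: canonical update order of the random blocks
BLOCK_ORDER = ("L", "G", "GxG", "GxE", "GxGxE")
#: blocks whose effects are drawn independently per environment
PER_ENV_BLOCKS = frozenset({"GxE", "GxGxE"})
#: line-level kernel backing each random block
_BLOCK_KERNEL_KEY = {"L": "L", "G": "G", "GxG": "GA", "GxE": "G", "GxGxE": "GA"}

__all__ = [
    "MODEL_BLOCKS",
    "ModelSpec",
    "PriorSpec",
    "GibbsSettings",
    "PosteriorSummary",
    "GibbsResult",
    "GibbsSampler",
    "build_model",
    "default_priors",
    "run_gibbs",
    "fit",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelSpec:
    """Which effect blocks a model includes and the kernels backing them."""

    model_id: Optional[int]
    blocks: tuple
    kernels: Dict[str, Kernel]  # random block name -> line-level kernel
    inc: IncidenceSet

    def __post_init__(self) -> None:
        if "E" not in self.blocks:
            raise ValueError("every model includes the fixed environment block E")
        for name in self.random_blocks:
            if name not in self.kernels:
                raise ValueError(f"missing kernel for block {name!r}")

    @property
    def random_blocks(self) -> tuple:
        return tuple(b for b in BLOCK_ORDER if b in self.blocks)


@dataclasses.dataclass
class PriorSpec:
    """Hyperparameters: flat Gaussian for fixed effects, scaled-inverse-chi^2
    (df, S) per variance component; residual variance fixed at 1, never sampled."""

    fixed_effect_variance: float = DEFAULT_FIXED_PRIOR_VARIANCE
    df: float = DEFAULT_DF
    scales: Dict[str, float] = dataclasses.field(default_factory=dict)
    residual_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("prior scales must be positive")
        if self.residual_variance != 1.0:
            raise ValueError("residual variance is fixed at 1 for identifiability")


@dataclasses.dataclass
class GibbsSettings:
    iterations: int = DEFAULT_ITERATIONS
    burnin: int = DEFAULT_BURNIN
    thin: int = DEFAULT_THIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.n_retained < 1:
            raise ValueError("settings retain no draws; increase iterations or reduce thinning")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


def build_model(model_id: int, kernels: Mapping[str, Kernel], inc: IncidenceSet) -> ModelSpec:
    """Resolve a model id (1..9) into its effect blocks and kernels.

    ``kernels`` supplies the line-level G and (for epistasis models) GA; the
    IID line kernel L is built internally.
    """
    if model_id not in MODEL_BLOCKS:
        raise ValueError(f"model id must be in 1..9, got {model_id!r}")
    blocks = MODEL_BLOCKS[model_id]
    resolved: Dict[str, Kernel] = {}
    for name in blocks:
        if name == "E":
            continue
        key = _BLOCK_KERNEL_KEY[name]
        if key == "L":
            resolved[name] = identity_kernel(inc.line_ids)
        elif key in kernels:
            resolved[name] = kernels[key]
        else:
            raise ValueError(f"model {model_id} block {name!r} requires kernel {key!r}")
    return ModelSpec(model_id, blocks, resolved, inc)


def default_priors(spec: ModelSpec, df: float = DEFAULT_DF) -> PriorSpec:
    """Scale parameters from the 50% prior variance-split rule.

    With K random blocks, each block's scale S_k = (df + 2) / (K * mean
    diagonal of its kernel), so the prior mode S_k/(df+2) puts a liability
    variance of 1/K on each block -- jointly matching the unit residual
    variance (50% signal / 50% error a priori).  Line-level blocks use the
    line-kernel diagonal; interaction blocks use the record-level diagonal
    (the kernel as it enters the model).
    """
    if df <= 0:
        raise ValueError("prior degrees of freedom must be positive")
    random = spec.random_blocks
    scales: Dict[str, float] = {}
    if random:
        k = len(random)
        for name in random:
            kern = spec.kernels[name]
            if name in PER_ENV_BLOCKS:
                mean_diag = float(np.mean(np.diag(kern.matrix)[spec.inc.line_codes]))
            else:
                mean_diag = kern.mean_diagonal()
            if mean_diag <= 0:
                raise ValueError(f"kernel for block {name!r} has nonpositive mean diagonal")
            scales[name] = (df + 2.0) / (k * mean_diag)
    return PriorSpec(df=df, scales=scales)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Segment:
    """One independent coefficient group of a block (one env, or the whole set)."""

    rows: np.ndarray        # record indices covered by this segment
    lines: np.ndarray       # line code per covered record
    V: np.ndarray           # eigenvectors of W'W (q x q)
    D: np.ndarray           # eigenvalues of W'W (q,)
    env: Optional[int]
    u: np.ndarray           # current coefficients in the kernel eigenbasis
    b: np.ndarray           # current line-level effects F @ u
    contrib: np.ndarray     # current per-record contribution b[lines]


class _Block:
    """Precomputed design of one random effect block in its kernel eigenbasis."""

    def __init__(self, name: str, kernel: Kernel, inc: IncidenceSet):
        self.name = name
        self.F = kernel_factor(kernel)          # J x q, K = F F'
        self.q = self.F.shape[1]
        n_lines = self.F.shape[0]
        self.per_env = name in PER_ENV_BLOCKS
        groups = (
            [(i, np.flatnonzero(inc.env_codes == i)) for i in range(len(inc.env_ids))]
            if self.per_env
            else [(None, np.arange(inc.n_records))]
        )
        self.segments = []
        for env, rows in groups:
            lines = inc.line_codes[rows]
            counts = np.bincount(lines, minlength=n_lines).astype(float)
            wtw = self.F.T @ (self.F * counts[:, None])
            d, v = np.linalg.eigh(wtw)
            self.segments.append(
                _Segment(
                    rows=rows,
                    lines=lines,
                    V=v,
                    D=np.clip(d, 0.0, None),
                    env=env,
                    u=np.zeros(self.q),
                    b=np.zeros(n_lines),
                    contrib=np.zeros(len(rows)),
                )
            )

    @property
    def dimension(self) -> int:
        """Total number of eigen-coefficients (q per segment)."""
        return self.q * len(self.segments)

    def sum_squares(self) -> float:
        """SS = b' K^- b, computed as u'u in the eigenbasis."""
        return float(sum(seg.u @ seg.u for seg in self.segments))

    def line_effects(self) -> np.ndarray:
        """Current line-level effects: (J,) or (I, J) for per-env blocks."""
        if self.per_env:
            return np.stack([seg.b for seg in self.segments])
        return self.segments[0].b.copy()


class GibbsSampler:
    """Mutable MCMC state plus the full-conditional update steps.

    The invariants maintained after every sweep: thresholds strictly
    increasing with gamma_1 = 0, every liability strictly inside its observed
    category's interval, all variance components positive, residual variance
    exactly 1.
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        spec: ModelSpec,
        priors: Optional[PriorSpec] = None,
        seed: int = 0,
    ):
        if pheno.n_records != spec.inc.n_records:
            raise ValueError("phenotype table and incidence set differ in record count")
        self.pheno = pheno
        self.spec = spec
        self.priors = priors if priors is not None else default_priors(spec)
        for name in spec.random_blocks:
            if name not in self.priors.scales:
                raise ValueError(f"priors missing a scale for block {name!r}")
        self.rng = np.random.default_rng(seed)

        self.y = pheno.score
        self.n = pheno.n_records
        self.C = pheno.n_categories
        self.env_codes = spec.inc.env_codes
        self.I = len(spec.inc.env_ids)
        self.env_counts = np.bincount(self.env_codes, minlength=self.I).astype(float)

        self.blocks = {name: _Block(name, spec.kernels[name], spec.inc) for name in spec.random_blocks}
        self.sigma2 = {
            name: self.priors.scales[name] / (self.priors.df + 2.0) for name in self.blocks
        }

        self._init_location()
        self.iteration = 0
        self.sample_liabilities()

    # -- initialization ----------------------------------------------------

    def _init_location(self) -> None:
        """Start thresholds/fixed effects at probit transforms of the observed
        category frequencies; random effects start at zero."""
        counts = np.bincount(self.y, minlength=self.C + 1)[1:].astype(float)
        cum = np.cumsum(counts) / counts.sum()
        cum = np.clip(cum[:-1], 1e-3, 1.0 - 1e-3)
        cum = np.maximum.accumulate(cum + 1e-9 * np.arange(self.C - 1))
        g = ndtri(cum)
        self.gamma = g - g[0]  # finite thresholds, gamma[0] = 0

        beta = np.zeros(self.I)
        for i in range(self.I):
            f1 = np.mean(self.y[self.env_codes == i] == 1)
            beta[i] = -ndtri(np.clip(f1, 1e-3, 1.0 - 1e-3))
        self.beta = beta
        self.eta = self.beta[self.env_codes].copy()
        self.liab = np.zeros(self.n)

    # -- derived quantities ------------------------------------------------

    @property
    def gamma_full(self) -> np.ndarray:
        """Thresholds padded with -inf/+inf: length C + 1."""
        return np.concatenate(([-np.inf], self.gamma, [np.inf]))

    def beta_conditional(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and precision of the fixed-effect full conditional."""
        resid_plus = self.liab - self.eta + self.beta[self.env_codes]
        sums = np.bincount(self.env_codes, weights=resid_plus, minlength=self.I)
        prec = self.env_counts + 1.0 / self.priors.fixed_effect_variance
        return sums / prec, prec

    def block_conditional_mean(self, name: str) -> np.ndarray:
        """Full-conditional mean of a block's line-level effects given the
        current liabilities and all other effects ((J,) or (I, J))."""
        block = self.blocks[name]
        s2 = self.sigma2[name]
        means = []
        for seg in block.segments:
            r = self.liab[seg.rows] - self.eta[seg.rows] + seg.contrib
            t = block.F.T @ np.bincount(seg.lines, weights=r, minlength=block.F.shape[0])
            mean_u = seg.V @ ((seg.V.T @ t) / (seg.D + 1.0 / s2))
            means.append(block.F @ mean_u)
        return np.stack(means) if block.per_env else means[0]

    # -- full-conditional updates -----------------------------------------

    def sample_liabilities(self, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Draw each liability from N(eta, 1) truncated to its category interval."""
        rng = rng if rng is not None else self.rng
        gf = self.gamma_full
        a = gf[self.y - 1]
        b = gf[self.y]
        pa = ndtr(a - self.eta)
        pb = ndtr(b - self.eta)
        u = rng.uniform(size=self.n)
        p = np.clip(pa + u * (pb - pa), 1e-15, 1.0 - 1e-16)
        liab = self.eta + ndtri(p)
        # enforce the open interval strictly (guards against tail round-off)
        lo_f = np.isfinite(a)
        hi_f = np.isfinite(b)
        liab[lo_f] = np.maximum(liab[lo_f], a[lo_f] + 1e-12)
        liab[hi_f] = np.minimum(liab[hi_f], b[hi_f] - 1e-12)
        bad = (lo_f & (liab <= a)) | (hi_f & (liab >= b))
        if bad.any():  # pragma: no cover - extreme-tail rescue
            mid = np.where(lo_f & hi_f, (a + b) / 2.0, np.where(hi_f, b - 0.5, a + 0.5))
            liab[bad] = mid[bad]
        self.liab = liab
        return liab

    def sample_thresholds(self, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Albert-Chib uniform full conditionals for gamma_2..gamma_{C-1}.

        gamma_1 stays 0.  Empty categories fall back to the adjacent
        thresholds as interval ends; an unbounded interval (empty topmost
        categories) leaves the threshold unchanged.
        """
        rng = rng if rng is not None else self.rng
        for c in range(2, self.C):  # threshold gamma_c sits at self.gamma[c - 1]
            below = self.liab[self.y == c]
            above = self.liab[self.y == c + 1]
            lower = below.max() if below.size else self.gamma[c - 2]
            upper = above.min() if above.size else (
                self.gamma[c] if c - 1 < self.C - 2 else np.inf
            )
            if not np.isfinite(upper):
                logger.debug("threshold gamma_%d has an unbounded interval; kept at %.4f", c, self.gamma[c - 1])
                continue
            if upper <= lower:
                raise RuntimeError(
                    f"degenerate threshold interval for gamma_{c}: ({lower}, {upper})"
                )
            self.gamma[c - 1] = rng.uniform(lower, upper)
        return self.gamma

    def sample_location_effects(self, rng: Optional[np.random.Generator] = None) -> None:
        """Gaussian full-conditional draws for fixed effects and every random block."""
        rng = rng if rng is not None else self.rng
        mean, prec = self.beta_conditional()
        new_beta = mean + rng.standard_normal(self.I) / np.sqrt(prec)
        self.eta += (new_beta - self.beta)[self.env_codes]
        self.beta = new_beta

        for name, block in self.blocks.items():
            inv_s2 = 1.0 / self.sigma2[name]
            for seg in block.segments:
                r = self.liab[seg.rows] - self.eta[seg.rows] + seg.contrib
                t = block.F.T @ np.bincount(seg.lines, weights=r, minlength=block.F.shape[0])
                denom = seg.D + inv_s2
                coef = (seg.V.T @ t) / denom + rng.standard_normal(block.q) / np.sqrt(denom)
                seg.u = seg.V @ coef
                seg.b = block.F @ seg.u
                new_contrib = seg.b[seg.lines]
                self.eta[seg.rows] += new_contrib - seg.contrib
                seg.contrib = new_contrib

    def sample_variances(self, rng: Optional[np.random.Generator] = None) -> Dict[str, float]:
        """Scaled-inverse-chi^2 draws: sigma_k^2 = (S_k + SS_k) / chi^2_{df + q_k}.

        SS_k = b'K^- b via the eigenbasis; the residual variance is never
        updated (fixed at 1).
        """
        rng = rng if rng is not None else self.rng
        for name, block in self.blocks.items():
            ss = block.sum_squares()
            s = self.priors.scales[name]
            draw = (s + ss) / rng.chisquare(self.priors.df + block.dimension)
            self.sigma2[name] = max(draw, _VAR_FLOOR)
        return self.sigma2

    def step(self) -> None:
        """One full Gibbs sweep: liabilities, thresholds, locations, variances."""
        self.sample_liabilities()
        self.sample_thresholds()
        self.sample_location_effects()
        self.sample_variances()
        self.iteration += 1


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorSummary:
    """Posterior mean/SD table plus the settings that produced it."""

    table: pd.DataFrame  # index: parameter, columns: mean, sd
    n_draws: int
    settings: GibbsSettings

    def mean(self, parameter: str) -> float:
        return float(self.table.loc[parameter, "mean"])

    def sd(self, parameter: str) -> float:
        return float(self.table.loc[parameter, "sd"])


@dataclasses.dataclass
class GibbsResult:
    """Retained draws and posterior summaries of one fitted chain."""

    summary: PosteriorSummary
    draws: Dict[str, np.ndarray]
    spec: ModelSpec
    priors: PriorSpec
    settings: GibbsSettings
    env_ids: tuple
    line_ids: tuple
    n_categories: int

    @property
    def random_blocks(self) -> tuple:
        return self.spec.random_blocks

    def variance_estimates(self) -> Dict[str, float]:
        """Posterior mean variance components keyed by block name."""
        return {name: float(self.draws[f"sigma2_{name}"].mean()) for name in self.random_blocks}


def run_gibbs(
    pheno: PhenotypeTable,
    spec: ModelSpec,
    priors: Optional[PriorSpec] = None,
    settings: Optional[GibbsSettings] = None,
) -> GibbsResult:
    """Fit one model by Gibbs sampling and return retained draws + summaries.

    Sweep order: liabilities -> thresholds -> fixed effects -> random blocks
    -> variances.  Post-burn-in draws are retained every ``thin`` sweeps;
    the chain is a pure function of the settings seed.
    """
    settings = settings if settings is not None else GibbsSettings()
    sampler = GibbsSampler(pheno, spec, priors, seed=settings.seed)
    n_draws = settings.n_retained
    I, C = sampler.I, sampler.C

    draws: Dict[str, np.ndarray] = {
        "beta": np.empty((n_draws, I)),
        "gamma": np.empty((n_draws, C - 1)),
    }
    for name, block in sampler.blocks.items():
        draws[f"sigma2_{name}"] = np.empty(n_draws)
        shape = (n_draws, len(block.segments), block.F.shape[0]) if block.per_env \
            else (n_draws, block.F.shape[0])
        draws[f"effects_{name}"] = np.empty(shape)

    logger.info(
        "Gibbs chain: model %s, %d records, %d iterations (burn-in %d, thin %d, seed %d)",
        spec.model_id, pheno.n_records, settings.iterations, settings.burnin,
        settings.thin, settings.seed,
    )
    d = 0
    for t in range(1, settings.iterations + 1):
        sampler.step()
        if t > settings.burnin and (t - settings.burnin) % settings.thin == 0:
            draws["beta"][d] = sampler.beta
            draws["gamma"][d] = sampler.gamma
            for name, block in sampler.blocks.items():
                draws[f"sigma2_{name}"][d] = sampler.sigma2[name]
                draws[f"effects_{name}"][d] = block.line_effects()
            d += 1

    rows = {}
    for i, env in enumerate(spec.inc.env_ids):
        rows[f"beta_{env}"] = draws["beta"][:, i]
    for c in range(2, C):
        rows[f"gamma_{c}"] = draws["gamma"][:, c - 1]
    for name in sampler.blocks:
        rows[f"sigma2_{name}"] = draws[f"sigma2_{name}"]
    table = pd.DataFrame(
        {
            "mean": {k: float(v.mean()) for k, v in rows.items()},
            "sd": {k: float(v.std(ddof=1)) for k, v in rows.items()},
        }
    )
    summary = PosteriorSummary(table, n_draws, settings)
    return GibbsResult(
        summary=summary,
        draws=draws,
        spec=spec,
        priors=sampler.priors,
        settings=settings,
        env_ids=tuple(spec.inc.env_ids),
        line_ids=tuple(spec.inc.line_ids),
        n_categories=C,
    )


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def prepare_kernels(geno: RawGenotypes, model_id: int, qc: bool = True) -> Dict[str, Kernel]:
    """QC + standardization + the line-level kernels a model needs."""
    if qc:
        geno, _ = qc_markers(geno)
    markers = standardize_markers(geno)
    kernels = {"G": compute_grm(markers)}
    blocks = MODEL_BLOCKS.get(model_id, ())
    if "GxG" in blocks or "GxGxE" in blocks:
        kernels["GA"] = epistasis_kernel(kernels["G"])
    return kernels


def fit(
    pheno: PhenotypeTable,
    geno: RawGenotypes,
    model_id: int,
    settings: Optional[GibbsSettings] = None,
    df: float = DEFAULT_DF,
    qc: bool = True,
) -> GibbsResult:
    """End-to-end fit: marker QC, kernel construction, priors, Gibbs chain."""
    kernels = prepare_kernels(geno, model_id, qc=qc)
    inc = build_incidence(pheno, kernels["G"].ids)
    spec = build_model(model_id, kernels, inc)
    priors = default_priors(spec, df=df)
    return run_gibbs(pheno, spec, priors, settings)
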