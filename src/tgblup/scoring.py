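"""Predictive category probabilities, Brier scoring, cross-validation, and
variance-partition summaries for threshold GBLUP fits.

The cumulative-probit link turns a linear predictor eta and thresholds gamma
into category probabilities

    pi_c = Phi(gamma_c - eta) - Phi(gamma_{c-1} - eta),

with gamma_0 = -inf and gamma_C = +inf.  Forecast quality is measured by the
Brier score, the mean squared distance between the predicted probability
vector and the one-hot observed category,

    BS = n^-1 sum_i sum_c (pi_ic - d_ic)^2,

which ranges over [0, 2]; BS/2 is reported so the score lies in [0, 1]
(lower is better).  Cross-validation assigns records -- not lines -- to
training/testing completely at random (a CV2-style design: a line can be
trained in one environment and tested in another), refits the model per
partition, and summarizes scaled Brier scores per environment.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_io import PhenotypeTable, RawGenotypes
from .kernels import build_incidence
from .sampler import (
    GibbsResult,
    GibbsSettings,
    build_model,
    default_priors,
    prepare_kernels,
    run_gibbs,
)

logger = logging.getLogger("tgblup")

__all__ = [
    "PredictiveDistribution",
    "BrierResult",
    "VariancePartition",
    "CVResult",
    "category_probabilities",
    "posterior_probabilities",
    "ordinal_log_likelihood",
    "brier_score",
    "cross_validate",
    "variance_partition",
    "relative_gain",
]


# ---------------------------------------------------------------------------
# link
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PredictiveDistribution:
    """Per-record category probabilities and the (mean) link values behind them."""

    probabilities: np.ndarray  # (n, C)
    eta: np.ndarray            # (n,) posterior-mean linear predictor
    gamma: np.ndarray          # (C-1,) thresholds used (posterior mean)
    mode: str

    def __post_init__(self) -> None:
        p = self.probabilities
        if np.any(p < -1e-12):
            raise ValueError("negative category probability")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("category probabilities do not sum to 1")

    @property
    def n_records(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_categories(self) -> int:
        return self.probabilities.shape[1]


def category_probabilities(gamma: Sequence[float], eta: Sequence[float]) -> np.ndarray:
    """Cumulative-probit probabilities for each record and category.

    ``gamma`` are the C-1 finite thresholds (strictly increasing), ``eta``
    the per-record linear predictors; returns an (n, C) array of
    pi_c = Phi(gamma_c - eta) - Phi(gamma_{c-1} - eta).
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if gamma.ndim != 1 or np.any(np.diff(gamma) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    cdf = ndtr(gamma[None, :] - eta[:, None])  # (n, C-1)
    n, cm1 = cdf.shape
    probs = np.empty((n, cm1 + 1))
    probs[:, 0] = cdf[:, 0]
    probs[:, 1:-1] = np.diff(cdf, axis=1)
    probs[:, -1] = 1.0 - cdf[:, -1]
    return probs


def _map_records(result: GibbsResult, records) -> tuple[np.ndarray, np.ndarray]:
    """env/line codes of prediction records against a fit's id order."""
    if isinstance(records, PhenotypeTable):
        records = records.records
    env_pos = {e: i for i, e in enumerate(result.env_ids)}
    line_pos = {l: j for j, l in enumerate(result.line_ids)}
    unknown_env = sorted({e for e in records["env"] if e not in env_pos})
    unknown_line = sorted({l for l in records["line"] if l not in line_pos})
    if unknown_env or unknown_line:
        raise ValueError(
            f"records reference environments/lines unknown to the fit: "
            f"envs={unknown_env[:5]}, lines={unknown_line[:5]}"
        )
    e = records["env"].map(env_pos).to_numpy(dtype=int)
    l = records["line"].map(line_pos).to_numpy(dtype=int)
    return e, l


def posterior_probabilities(
    result: GibbsResult,
    records: Union[PhenotypeTable, pd.DataFrame],
    mode: str = "per-draw-average",
) -> PredictiveDistribution:
    """Predictive distribution pi-hat for each record of a fitted model.

    ``per-draw-average`` evaluates the link at every retained draw and
    averages the probabilities (full posterior predictive); ``plug-in``
    evaluates it once at the posterior means.
    """
    if mode not in ("per-draw-average", "plug-in"):
        raise ValueError(f"unknown mode {mode!r}")
    e, l = _map_records(result, records)
    eta_draws = result.draws["beta"][:, e].copy()  # (D, n)
    for name in result.random_blocks:
        eff = result.draws[f"effects_{name}"]
        eta_draws += eff[:, e, l] if eff.ndim == 3 else eff[:, l]
    gamma_draws = result.draws["gamma"]  # (D, C-1)
    eta_mean = eta_draws.mean(axis=0)
    gamma_mean = gamma_draws.mean(axis=0)

    if mode == "plug-in":
        probs = category_probabilities(gamma_mean, eta_mean)
    else:
        n = eta_draws.shape[1]
        c_minus_1 = gamma_draws.shape[1]
        probs = np.empty((n, c_minus_1 + 1))
        prev = np.zeros_like(eta_draws)
        for c in range(c_minus_1):
            cur = ndtr(gamma_draws[:, c][:, None] - eta_draws)
            probs[:, c] = (cur - prev).mean(axis=0)
            prev = cur
        probs[:, -1] = (1.0 - prev).mean(axis=0)
    return PredictiveDistribution(probs, eta_mean, gamma_mean, mode)


# ---------------------------------------------------------------------------
# scoring rules
# ---------------------------------------------------------------------------

def _prob_array(probs) -> np.ndarray:
    if isinstance(probs, PredictiveDistribution):
        return probs.probabilities
    return np.atleast_2d(np.asarray(probs, dtype=float))


def ordinal_log_likelihood(probs, observed: Sequence[int]) -> float:
    """Sum of log predictive probabilities of the observed categories."""
    p = _prob_array(probs)
    observed = np.asarray(observed, dtype=int)
    if len(observed) != p.shape[0]:
        raise ValueError("probabilities and observations differ in length")
    p_obs = p[np.arange(len(observed)), observed - 1]
    if np.any(p_obs <= 0.0):
        warnings.warn("zero predictive probability for an observed category; log-likelihood is -inf")
        return float("-inf")
    return float(np.log(p_obs).sum())


@dataclasses.dataclass
class BrierResult:
    """Raw Brier score (range [0, 2]) and its halved, [0, 1]-bounded form."""

    n_records: int
    raw: float
    scaled: float


def brier_score(probs, observed: Sequence[int]) -> BrierResult:
    """Brier score of predictive distributions against observed categories.

    Raw BS = n^-1 sum_i sum_c (pi_ic - d_ic)^2 with d the one-hot observed
    category; the scaled score is BS/2.  Lower is better.
    """
    p = _prob_array(probs)
    observed = np.asarray(observed, dtype=int)
    if len(observed) != p.shape[0]:
        raise ValueError("probabilities and observations differ in length")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probabilities must sum to 1 per record")
    if observed.min() < 1 or observed.max() > p.shape[1]:
        raise ValueError("observed categories outside 1..C")
    d = np.zeros_like(p)
    d[np.arange(len(observed)), observed - 1] = 1.0
    raw = float(np.mean(np.sum((p - d) ** 2, axis=1)))
    return BrierResult(len(observed), raw, raw / 2.0)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVResult:
    """Per-partition scaled Brier scores and their per-environment summary."""

    scores: pd.DataFrame    # columns: partition, env, n_test, brier
    summary: pd.DataFrame   # columns: env, mean, min, max
    model_id: int
    seed: int


def _draw_partition(
    rng: np.random.Generator,
    pheno: PhenotypeTable,
    n_test: int,
    max_tries: int = 1000,
) -> np.ndarray:
    """Test-record indices with every environment present in both subsets."""
    n = pheno.n_records
    for attempt in range(max_tries):
        test = rng.choice(n, size=n_test, replace=False)
        in_test = np.zeros(n, dtype=bool)
        in_test[test] = True
        test_envs = set(pheno.env_index[in_test])
        train_envs = set(pheno.env_index[~in_test])
        if len(test_envs) == pheno.n_environments and len(train_envs) == pheno.n_environments:
            if attempt:
                logger.info("resampled CV partition %d time(s) to cover all environments", attempt)
            return np.sort(test)
    raise RuntimeError("could not draw a partition covering every environment")


def cross_validate(
    pheno: PhenotypeTable,
    geno: RawGenotypes,
    model_id: int,
    partitions: int = 20,
    test_fraction: float = 0.20,
    seed: int = 0,
    settings: Optional[GibbsSettings] = None,
    mode: str = "per-draw-average",
    df: float = 5.0,
    qc: bool = True,
) -> CVResult:
    """Random-partition cross-validation scored by the scaled Brier score.

    Records are assigned to the test set completely at random (CV2-style);
    the model is refitted on training records only, test records are scored,
    and scaled Brier scores are summarized per environment over partitions.
    ``test_fraction = 0.0`` is the degenerate in-sample diagnostic (test set
    equals the training set); any other value outside (0, 1) errors.
    """
    if not (0.0 <= test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1) (or exactly 0 for in-sample scoring)")
    if partitions < 1:
        raise ValueError("at least one partition is required")
    settings = settings if settings is not None else GibbsSettings()
    kernels = prepare_kernels(geno, model_id, qc=qc)
    line_ids = kernels["G"].ids
    rng = np.random.default_rng(seed)
    n = pheno.n_records
    n_test = max(1, int(round(test_fraction * n)))

    rows = []
    for part in range(partitions):
        if test_fraction == 0.0:
            test_idx = np.arange(n)
            train_idx = np.arange(n)
        else:
            test_idx = _draw_partition(rng, pheno, n_test)
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            train_idx = np.flatnonzero(mask)
        train = pheno.subset(train_idx)
        inc = build_incidence(train, line_ids)
        spec = build_model(model_id, kernels, inc)
        priors = default_priors(spec, df=df)
        part_settings = dataclasses.replace(
            settings, seed=int((settings.seed + 1_009 * (part + 1)) % 2**31)
        )
        result = run_gibbs(train, spec, priors, part_settings)

        test_records = pheno.records.iloc[test_idx]
        pred = posterior_probabilities(result, test_records, mode=mode)
        test_scores = pheno.score[test_idx]
        test_envs = pheno.records["env"].to_numpy()[test_idx]
        for env in pheno.env_ids:
            sel = test_envs == env
            bs = brier_score(pred.probabilities[sel], test_scores[sel])
            rows.append(
                {"partition": part, "env": env, "n_test": int(sel.sum()), "brier": bs.scaled}
            )
    scores = pd.DataFrame(rows)
    summary = (
        scores.groupby("env", sort=False)["brier"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )
    return CVResult(scores, summary, model_id, seed)


# ---------------------------------------------------------------------------
# variance partition and gains
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VariancePartition:
    """Total liability variance (components + unit error) and shares."""

    components: Dict[str, float]
    total: float
    percentages: Dict[str, float]  # includes the "error" share
    residual: float = 1.0

    def total_ratio(self, other: "VariancePartition") -> float:
        """How many times larger this model's total variance is than another's."""
        return self.total / other.total


def variance_partition(components: Mapping[str, float], residual: float = 1.0) -> VariancePartition:
    """Partition the liability variance of one model.

    Total = sum of component variances + the (unit) error variance; each
    percentage is 100 * v / total.
    """
    comps = {k: float(v) for k, v in components.items()}
    for k, v in comps.items():
        if v < 0:
            raise ValueError(f"negative variance component {k!r}: {v}")
    total = sum(comps.values()) + residual
    percentages = {k: 100.0 * v / total for k, v in comps.items()}
    percentages["error"] = 100.0 * residual / total
    return VariancePartition(comps, total, percentages, residual)


def relative_gain(bs_reference: float, bs_improved: float) -> float:
    """Percentage prediction-ability gain of an improved (lower) Brier score
    over a reference: 100 * (BS_ref - BS_new) / BS_new."""
    if bs_reference <= 0 or bs_improved <= 0:
        raise ValueError("Brier scores must be positive")
    return 100.0 * (bs_reference - bs_improved) / bs_improved
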