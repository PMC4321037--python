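"""Shared test construction helpers."""

import numpy as np
import pandas as pd

import tgblup as tg


def make_pheno(env, line, score, C=None):
    """Build a PhenotypeTable from parallel sequences, auto-numbering reps."""
    df = pd.DataFrame({"env": env, "line": line, "score": score})
    df["rep"] = df.groupby(["env", "line"]).cumcount() + 1
    return tg.PhenotypeTable(df[["env", "line", "rep", "score"]], C or int(max(score)))


def batch_means_se(draws, n_batches=20):
    """Monte-Carlo standard error of a chain mean via batch means."""
    draws = np.asarray(draws)
    usable = (len(draws) // n_batches) * n_batches
    batches = draws[:usable].reshape(n_batches, -1).mean(axis=1)
    return batches.std(ddof=1) / np.sqrt(n_batches)


def naive_threshold_gibbs(y, env, line, G, C, iters, burnin, seed, df=5.0, S=None,
                          fixed_var=1e10):
    """Independent reference Gibbs sampler for the single-kernel model.

    Deliberately different implementation choices from the package sampler:
    explicit pseudo-inverse of the kernel, dense multivariate-normal solves,
    scipy.stats.truncnorm liabilities.  Used as a two-implementation oracle.
    """
    from scipy.stats import truncnorm

    rng = np.random.default_rng(seed)
    n, J, I = len(y), G.shape[0], env.max() + 1
    if S is None:
        S = (df + 2.0) / np.mean(np.diag(G))
    lam, U = np.linalg.eigh(G)
    keep = lam > 1e-10 * lam.max()
    Ginv = (U[:, keep] / lam[keep]) @ U[:, keep].T
    q = int(keep.sum())
    P = U[:, keep] @ U[:, keep].T  # projector onto the kernel column space

    Z = np.zeros((n, J)); Z[np.arange(n), line] = 1.0
    X = np.zeros((n, I)); X[np.arange(n), env] = 1.0
    gamma = np.concatenate(([-np.inf, 0.0], np.linspace(0.5, 0.5 * (C - 2), C - 2), [np.inf]))
    beta, g, s2 = np.zeros(I), np.zeros(J), 1.0
    keep_s2, keep_g2 = [], []
    for t in range(iters):
        mu = X @ beta + Z @ g
        liab = truncnorm.rvs(gamma[y - 1] - mu, gamma[y] - mu, loc=mu, scale=1.0,
                             random_state=rng)
        for c in range(2, C):
            lo = max(liab[y == c]) if np.any(y == c) else gamma[c - 1]
            hi = min(liab[y == c + 1]) if np.any(y == c + 1) else gamma[c + 1]
            if np.isfinite(hi):
                gamma[c] = rng.uniform(lo, hi)
        r = liab - Z @ g
        for i in range(I):
            m = env == i
            prec = m.sum() + 1.0 / fixed_var
            beta[i] = r[m].sum() / prec + rng.standard_normal() / np.sqrt(prec)
        r = liab - X @ beta
        Cmat = P @ (Z.T @ Z + Ginv / s2) @ P + (np.eye(J) - P)
        Cinv = np.linalg.inv(Cmat)
        L = np.linalg.cholesky((Cinv + Cinv.T) / 2 + 1e-12 * np.eye(J))
        g = P @ (Cinv @ (P @ (Z.T @ r)) + L @ rng.standard_normal(J))
        s2 = (S + g @ Ginv @ g) / rng.chisquare(df + q)
        if t >= burnin:
            keep_s2.append(s2)
            keep_g2.append(gamma[2] if C > 2 else np.nan)
    return np.array(keep_s2), np.array(keep_g2)
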