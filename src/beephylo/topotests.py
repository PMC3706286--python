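"""Topology hypothesis tests from per-tree site log-likelihoods.

Given a matrix of site log-likelihoods ℓ_ij (tree i, site j) produced by a
constrained ML search, these tests ask which topologies can be rejected
without re-optimizing trees, by resampling sites (RELL — resampling
estimated log-likelihoods):

* ``rell_bootstrap`` — site index multisets drawn once per replicate and
  applied to every tree, giving replicate log-likelihood totals.
* ``wsh_test`` — weighted Shimodaira–Hasegawa: the statistic for tree i is
  the maximum variance-standardized likelihood deficit max_j (L_j - L_i)/σ̂_ij;
  the null distribution comes from centered RELL replicates with the same
  standardization.  Conservative by construction.
* ``au_test`` — approximately unbiased test: bootstrap proportions are
  measured at several resample sizes r·n and the curve
  Φ⁻¹(1 - BP(r)) ≈ d√r + c/√r is fitted by weighted least squares; the
  p-value 1 - Φ(d - c) corrects the selection bias of naive BP.
* ``bic_posterior`` — posterior-probability approximation
  pp_i ∝ exp(-BIC_i/2), BIC_i = k_i ln(n) - 2 L_i.
* ``bonferroni`` — family-wise correction across the hypotheses tested.

The plain (unweighted) SH statistic is available via ``wsh_test(...,
weighted=False)`` but the weighted form is the default surfaced in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SiteLikelihoodMatrix",
    "AuFit",
    "rell_bootstrap",
    "wsh_test",
    "au_test",
    "bic_posterior",
    "bonferroni",
    "topology_test_report",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5..1.4


@dataclass
class SiteLikelihoodMatrix:
    labels: list[str]
    values: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("site-likelihood matrix must be 2-D")
        n_trees, n_sites = self.values.shape
        if n_trees < 2 or n_sites < 1:
            raise ValueError("need >= 2 trees and >= 1 site")
        if len(self.labels) != n_trees:
            raise ValueError("one label per tree required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite site log-likelihoods")

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    # -- PUZZLE/CONSEL ".sitelh" dialect -----------------------------------

    @classmethod
    def read_sitelh(cls, path) -> "SiteLikelihoodMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        n_trees, n_sites = int(tokens[0]), int(tokens[1])
        pos = 2
        labels, rows = [], []
        for i in range(n_trees):
            first = tokens[pos]
            try:
                float(first)
                labels.append(f"tree{i + 1}")
            except ValueError:
                labels.append(first)
                pos += 1
            rows.append([float(x) for x in tokens[pos:pos + n_sites]])
            pos += n_sites
        return cls(labels, np.array(rows))

    def write_sitelh(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_trees} {self.n_sites}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + " " + " ".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def read_csv(cls, path) -> "SiteLikelihoodMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


@dataclass
class AuFit:
    scales: np.ndarray
    bp: np.ndarray          # (n_trees, n_scales)
    d: np.ndarray           # signed distance per tree
    c: np.ndarray           # curvature per tree
    residual: np.ndarray    # WLS residual per tree (nan when degenerate)
    degenerate: np.ndarray  # bool per tree: BP pinned at 0 or 1 everywhere


# ---------------------------------------------------------------------------
# RELL machinery
# ---------------------------------------------------------------------------


def _resample_totals(
    values: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    resample_size: int | None = None,
    chunk: int = 2000,
) -> np.ndarray:
    """Replicate totals (n_reps, n_trees); one index multiset per replicate,
    shared by all trees.  Chunked so counts never exceed ~chunk x n_sites."""
    n_trees, n_sites = values.shape
    size = n_sites if resample_size is None else int(resample_size)
    p = np.full(n_sites, 1.0 / n_sites)
    out = np.empty((n_reps, n_trees))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        counts = rng.multinomial(size, p, size=m)
        out[done:done + m] = counts @ values.T
        done += m
    return out


def rell_bootstrap(
    m: SiteLikelihoodMatrix,
    n_reps: int = 10000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """RELL bootstrap replicate totals, shape (n_reps, n_trees)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _resample_totals(m.values, n_reps, rng)


# ---------------------------------------------------------------------------
# Weighted Shimodaira-Hasegawa
# ---------------------------------------------------------------------------


def _pairwise_sd(values: np.ndarray) -> np.ndarray:
    """σ̂_ij: sd estimate of the *total* log-likelihood difference between
    trees i and j: σ̂²_ij = n/(n-1) · Σ_s (δ_s - δ̄)², δ_s per-site diffs."""
    n_trees, n_sites = values.shape
    sd = np.zeros((n_trees, n_trees))
    if n_sites < 2:
        return sd  # single site: no variance estimate; pairs get skipped
    for i in range(n_trees):
        delta = values - values[i]  # (n_trees, n_sites)
        centered = delta - delta.mean(axis=1, keepdims=True)
        var = (n_sites / (n_sites - 1)) * (centered ** 2).sum(axis=1)
        sd[i] = np.sqrt(var)
    return sd


def wsh_test(
    m: SiteLikelihoodMatrix,
    n_reps: int = 10000,
    seed: int | np.random.Generator = 0,
    weighted: bool = True,
) -> np.ndarray:
    """(Weighted) Shimodaira-Hasegawa p-values per tree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = m.values
    n_trees = m.n_trees
    totals = m.totals()
    sd = _pairwise_sd(values) if weighted else np.ones((n_trees, n_trees))
    zero = sd <= 0
    np.fill_diagonal(zero, True)  # self-pairs never contribute
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sd = np.where(zero, 0.0, 1.0 / sd)

    reps = _resample_totals(values, n_reps, rng)       # (n_reps, n_trees)
    centered = reps - reps.mean(axis=0, keepdims=True)  # null-centered

    p = np.empty(n_trees)
    for i in range(n_trees):
        diffs_obs = (totals - totals[i]) * inv_sd[i]
        diffs_obs[zero[i]] = -np.inf
        stat_obs = diffs_obs.max() if np.any(~zero[i]) else 0.0

        null = (centered - centered[:, i:i + 1]) * inv_sd[i][None, :]
        null[:, zero[i]] = -np.inf
        stat_null = null.max(axis=1)
        if np.any(~zero[i]):
            p[i] = float(np.mean(stat_null >= stat_obs))
        else:
            p[i] = 1.0  # all comparators identical to tree i
    return p


# ---------------------------------------------------------------------------
# Approximately unbiased test
# ---------------------------------------------------------------------------


def _bp_with_ties(reps: np.ndarray) -> np.ndarray:
    """Bootstrap proportions; replicates tied for the top split equally."""
    top = reps.max(axis=1, keepdims=True)
    winners = np.isclose(reps, top, rtol=0.0, atol=1e-9)
    share = winners / winners.sum(axis=1, keepdims=True)
    return share.mean(axis=0)


def au_test(
    m: SiteLikelihoodMatrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_reps: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, AuFit]:
    """Approximately unbiased p-values via the multiscale bootstrap."""
    scales = np.asarray(sorted(scales), dtype=float)
    if scales.size < 2:
        raise ValueError("need at least 2 scales")
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_trees, n_sites = m.values.shape
    bp = np.empty((n_trees, scales.size))
    for s, r in enumerate(scales):
        size = max(1, int(round(r * n_sites)))
        reps = _resample_totals(m.values, n_reps, rng, resample_size=size)
        bp[:, s] = _bp_with_ties(reps)

    p = np.empty(n_trees)
    d = np.full(n_trees, np.nan)
    c = np.full(n_trees, np.nan)
    resid = np.full(n_trees, np.nan)
    degenerate = np.zeros(n_trees, dtype=bool)
    eps = 0.5 / n_reps
    for i in range(n_trees):
        bpi = bp[i]
        informative = (bpi > eps) & (bpi < 1 - eps)
        if informative.sum() < 2:
            # BP pinned at a boundary (possibly bar a stray replicate):
            # the signed-distance fit is undefined, force the boundary.
            degenerate[i] = True
            p[i] = 1.0 if bpi.mean() >= 0.5 else 0.0
            continue
        r = scales[informative]
        bpe = np.clip(bpi[informative], eps, 1 - eps)
        z = norm.ppf(1.0 - bpe)
        # design: z = d*sqrt(r) + c/sqrt(r); binomial WLS weights
        w = n_reps * norm.pdf(z) ** 2 / (bpe * (1 - bpe))
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
        d[i], c[i] = beta
        resid[i] = float(np.sum(w * (z - X @ beta) ** 2))
        p[i] = float(1.0 - norm.cdf(d[i] - c[i]))
    return p, AuFit(scales, bp, d, c, resid, degenerate)


# ---------------------------------------------------------------------------
# BIC posterior approximation and multiple-testing correction
# ---------------------------------------------------------------------------


def bic_posterior(
    m: SiteLikelihoodMatrix, k: Sequence[int] | int = 1
) -> np.ndarray:
    """pp_i = exp(-BIC_i/2) / Σ exp(-BIC_j/2), BIC_i = k_i ln(n) - 2 L_i."""
    totals = m.totals()
    karr = np.full(m.n_trees, k) if np.isscalar(k) else np.asarray(k, dtype=float)
    bic = karr * np.log(m.n_sites) - 2.0 * totals
    w = -bic / 2.0
    w -= w.max()  # overflow-safe
    e = np.exp(w)
    return e / e.sum()


def bonferroni(p: Sequence[float], alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni correction: reject iff p < alpha/m; adjusted p = min(1, p·m)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    m_tests = p.size
    threshold = alpha / m_tests
    return pd.DataFrame(
        {
            "p": p,
            "p_adjusted": np.minimum(1.0, p * m_tests),
            "reject": p < threshold,
            "threshold": threshold,
        }
    )


def topology_test_report(
    m: SiteLikelihoodMatrix,
    n_reps: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Table mirroring a CONSEL-style hypothesis-test summary."""
    ss = np.random.SeedSequence(seed)
    s_wsh, s_au = ss.spawn(2)
    p_wsh = wsh_test(m, n_reps=n_reps, seed=np.random.default_rng(s_wsh))
    p_au, _ = au_test(m, scales=scales, n_reps=n_reps, seed=np.random.default_rng(s_au))
    pp = bic_posterior(m)
    rej_wsh = bonferroni(p_wsh, alpha)
    rej_au = bonferroni(p_au, alpha)
    df = pd.DataFrame(
        {
            "hypothesis": m.labels,
            "lnL": m.totals(),
            "WSH": p_wsh,
            "AU": p_au,
            "BIC_pp": pp,
            "reject_WSH": rej_wsh["reject"],
            "reject_AU": rej_au["reject"],
        }
    )
    return df.sort_values("lnL", ascending=False).reset_index(drop=True)
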