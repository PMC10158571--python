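"""Phase-randomization surrogate inference for group-averaged ISCs.

Significance of a group-averaged ISC is assessed against an empirical null:
for each participant, 1000 surrogate time courses are generated by
phase-randomizing that participant's series (identical amplitude spectrum —
hence identical autocorrelation — with uniformly random Fourier phases), each
is correlated with the veridical leave-one-out average of the other
participants, and the resulting Fisher-z values are summarized by a Gaussian
(sample mean and sd).  The per-participant Gaussians are combined
analytically into the null of the group mean (mean of means; sd of the mean
of N independent draws), the observed group-average Fisher-z is z-scored
against it, and converted to a one-tailed p-value.  Families of tests are
corrected with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .isc import fisher_z, loo_isc
from .synthetic import _derive_seed


def phase_randomize(series: np.ndarray, seed, n_surrogates: int = 1) -> np.ndarray:
    """Surrogate series with the original amplitude spectrum and random phases.

    The DC bin (and the Nyquist bin for even lengths) keeps its phase so the
    output is real with the original mean; all other rFFT bins get phases
    drawn uniformly on [0, 2π), with Hermitian symmetry implied by the rFFT
    representation.

    Returns shape ``(n_surrogates, T)``; a single surrogate is squeezed to
    ``(T,)``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series too short to phase-randomize")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    n_bins = spec.size
    free = np.ones(n_bins, dtype=bool)
    free[0] = False
    if n % 2 == 0:
        free[-1] = False
    phases = np.tile(np.angle(spec), (n_surrogates, 1))
    phases[:, free] = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, free.sum()))
    surr = np.fft.irfft(amp * np.exp(1j * phases), n=n, axis=-1)
    return surr[0] if n_surrogates == 1 else surr


@dataclass
class SurrogateNull:
    """Gaussian fit to one participant's surrogate ISC distribution (Fisher-z scale)."""

    subject: int
    n_sim: int
    mu: float
    sigma: float


@dataclass
class GroupNull:
    """Analytic null of the group-averaged ISC."""

    mu: float
    sigma: float
    n_subjects: int


def subject_null(
    series_i: np.ndarray,
    others_avg: np.ndarray,
    n_sim: int = 1000,
    seed=0,
    subject: int = 0,
) -> SurrogateNull:
    """Null distribution of one participant's ISC.

    The participant's series is phase-randomized ``n_sim`` times; each
    surrogate is correlated with the *veridical* average of the remaining
    participants, Fisher-transformed, and the sample mean/sd of the
    surrogate values parameterize the Gaussian null.
    """
    x = np.asarray(series_i, dtype=float)
    y = np.asarray(others_avg, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input to subject_null")
    surr = phase_randomize(x, seed, n_surrogates=n_sim)
    surr_c = surr - surr.mean(axis=1, keepdims=True)
    y_c = y - y.mean()
    num = surr_c @ y_c
    denom = np.sqrt((surr_c**2).sum(axis=1) * (y_c**2).sum())
    r = num / denom
    z = fisher_z(r)
    return SurrogateNull(subject=subject, n_sim=n_sim, mu=float(z.mean()), sigma=float(z.std(ddof=1)))


def combine_null(nulls: Sequence[SurrogateNull]) -> GroupNull:
    """Null of the mean of N per-participant ISCs, assuming independence:
    mu = mean(mu_i), sigma = sqrt(sum sigma_i^2) / N."""
    if len(nulls) == 0:
        raise ValueError("no subject nulls to combine")
    mus = np.array([n.mu for n in nulls])
    sigmas = np.array([n.sigma for n in nulls])
    N = len(nulls)
    return GroupNull(mu=float(mus.mean()), sigma=float(np.sqrt((sigmas**2).sum()) / N), n_subjects=N)


def isc_pvalue(group_mean_z: float, null: GroupNull) -> float:
    """One-tailed (upper) p of the observed group-average Fisher-z under the
    combined Gaussian null."""
    if null.sigma <= 0:
        raise ValueError("null sigma must be positive")
    return float(stats.norm.sf((group_mean_z - null.mu) / null.sigma))


def fdr_bh(pvals: Sequence[float], q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject, p_adjusted).  Reject H_(i) for all i <= k where k is the
    largest index (1-based, p ascending) with p_(k) <= k*q/m; adjusted p are
    the step-up monotone cumulative minima of p_(i)*m/i.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = ranked <= thresh
    reject_sorted = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        reject_sorted[: k + 1] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    p_adj = np.zeros(m)
    reject[order] = reject_sorted
    p_adj[order] = adj_sorted
    return reject, p_adj


def group_null_test(
    series: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    label: Tuple = (),
) -> Dict[str, float]:
    """Full surrogate test for one (fROI, condition) cell.

    ``series`` is the subject × frame matrix of z-scored time courses.
    Returns the observed group-average Fisher-z, the combined null parameters,
    the null z-score, and the one-tailed p.  Surrogate seeds derive
    deterministically from ``seed`` and ``label`` (e.g., (froi, condition)).
    """
    Z = np.asarray(series, dtype=float)
    n = Z.shape[0]
    r_true = loo_isc(Z)
    z_true = fisher_z(r_true)
    group_z = float(np.nanmean(z_true))
    total = Z.sum(axis=0)
    nulls: List[SurrogateNull] = []
    for i in range(n):
        others = (total - Z[i]) / (n - 1)
        s = _derive_seed(seed, "null", *label, i)
        nulls.append(subject_null(Z[i], others, n_sim=n_sim, seed=s, subject=i))
    gnull = combine_null(nulls)
    zscore = (group_z - gnull.mu) / gnull.sigma
    return {
        "group_z": group_z,
        "null_mu": gnull.mu,
        "null_sigma": gnull.sigma,
        "null_zscore": float(zscore),
        "p": isc_pvalue(group_z, gnull),
        "n_subjects": n,
    }


def group_null_table(
    series_by_cell: Dict[Tuple[str, str], np.ndarray],
    n_sim: int = 1000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Surrogate tests for every (fROI, condition) cell, with BH-FDR across
    the family.  ``series_by_cell`` maps (froi, condition) to a subject ×
    frame matrix."""
    rows = []
    for (froi, condition), Z in series_by_cell.items():
        res = group_null_test(Z, n_sim=n_sim, seed=seed, label=(froi, condition))
        res.update({"froi": froi, "condition": condition})
        rows.append(res)
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(out["p"].to_numpy(), q=q)
    out["p_fdr"] = p_adj
    out["significant_fdr"] = reject
    return out
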