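"""Ploidy inference from the biallelic SNP allele-frequency spectrum.

At a heterozygous biallelic site in a genome of ploidy P, the alternate
allele is present in k of P copies (k = 1..P-1), so read-level allele
frequencies cluster at k/P: a diploid shows one peak at 1/2, a tetraploid
peaks at 1/4, 1/2 and 3/4. We model alt counts as a P-1 component binomial
mixture with fixed success probabilities

    p_k = (k/P)(1 - e) + (1 - k/P) e

(e = per-read error rate), estimate the component weights by EM, and select
P across a candidate range by BIC with P-2 free parameters (the weights; the
peak locations are fixed by P, and P=2 has a single forced component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


@dataclass
class PloidyFit:
    ploidy: int
    weights: np.ndarray            # w_1..w_{P-1}, sum to 1
    log_likelihood: float
    bic: float
    n_snps: int
    n_iterations: int = 0
    log_likelihood_path: List[float] = field(default_factory=list)


@dataclass
class PloidyResult:
    best: PloidyFit
    fits: Dict[int, PloidyFit]


# ---------------------------------------------------------------------------
# Filtering


def filter_snps(table: pd.DataFrame, min_depth: int = 20,
                af_bounds: Tuple[float, float] = (0.02, 0.98)) -> pd.DataFrame:
    """Keep sites with total depth >= min_depth and AF inside af_bounds.

    The AF bounds drop near-homozygous sites (sequencing errors at fixed
    positions) that would otherwise inflate the extreme components.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    total = table["ref_count"] + table["alt_count"]
    af = table["alt_count"] / total.replace(0, np.nan)
    lo, hi = af_bounds
    kept = table[(total >= min_depth) & (af >= lo) & (af <= hi)]
    if kept.empty:
        raise ValueError(
            "no SNP sites survive filtering; relax min_depth or af_bounds")
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mixture fit


def _component_probs(ploidy: int, error_rate: float) -> np.ndarray:
    k = np.arange(1, ploidy)
    return (k / ploidy) * (1 - error_rate) + (1 - k / ploidy) * error_rate


def _fit_one(alt: np.ndarray, total: np.ndarray, ploidy: int,
             error_rate: float, tol: float, max_iter: int) -> PloidyFit:
    p = _component_probs(ploidy, error_rate)
    n_comp = len(p)
    n = len(alt)
    # log Binom(alt | total, p_k); the binomial coefficient is shared across
    # components and cancels in the responsibilities but not in the lnL.
    log_coef = gammaln(total + 1) - gammaln(alt + 1) - gammaln(total - alt + 1)
    log_pmf = (log_coef[:, None] + alt[:, None] * np.log(p)[None, :]
               + (total - alt)[:, None] * np.log1p(-p)[None, :])
    w = np.full(n_comp, 1.0 / n_comp)
    path: List[float] = []
    n_iter = 0
    if n_comp == 1:
        lnl = float(log_pmf[:, 0].sum())
        path = [lnl]
    else:
        lnl = -np.inf
        for n_iter in range(1, max_iter + 1):
            joint = log_pmf + np.log(w)[None, :]
            site_lnl = logsumexp(joint, axis=1)
            new_lnl = float(site_lnl.sum())
            resp = np.exp(joint - site_lnl[:, None])
            w = resp.mean(axis=0)
            w = np.clip(w, 1e-300, None)
            w /= w.sum()
            path.append(new_lnl)
            if new_lnl - lnl < tol and n_iter > 1:
                lnl = new_lnl
                break
            lnl = new_lnl
    n_free = max(ploidy - 2, 0)
    bic = -2.0 * lnl + n_free * np.log(n)
    return PloidyFit(ploidy, w, lnl, float(bic), n, n_iter, path)


def fit_ploidy(table: pd.DataFrame, candidates: Sequence[int] = range(2, 9),
               error_rate: float = 0.01, tol: float = 1e-8,
               max_iter: int = 500) -> PloidyResult:
    """Fit the fixed-peak binomial mixture for each candidate ploidy and
    select the BIC-minimal one.

    EM starts from uniform weights (deterministic) and runs to a ``tol``
    log-likelihood increment or ``max_iter`` iterations. Fewer than 100
    sites triggers a warning-grade note but the fit proceeds.
    """
    import warnings as _warnings
    alt = table["alt_count"].to_numpy(dtype=float)
    total = (table["ref_count"] + table["alt_count"]).to_numpy(dtype=float)
    if len(alt) == 0:
        raise ValueError("no SNP sites to fit")
    if (total < 1).any():
        raise ValueError("every site needs at least one read")
    if len(alt) < 100:
        _warnings.warn(f"only {len(alt)} sites after filtering; ploidy "
                       "selection is unreliable below ~100 sites")
    if np.ptp(alt / total) == 0 and total.max() == 1:
        raise ValueError("degenerate input: identical allele frequencies at "
                         "depth 1 carry no ploidy signal")
    fits: Dict[int, PloidyFit] = {}
    for ploidy in sorted(set(int(c) for c in candidates)):
        if ploidy < 2:
            raise ValueError("candidate ploidies must be >= 2")
        fits[ploidy] = _fit_one(alt, total, ploidy, error_rate, tol, max_iter)
    best = min(fits.values(), key=lambda f: (f.bic, f.ploidy))
    return PloidyResult(best, fits)


# ---------------------------------------------------------------------------
# AF spectrum


def af_histogram(table: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Normalized histogram of alt/(ref+alt) over [0, 1]."""
    if bins < 10:
        raise ValueError("use at least 10 bins")
    total = (table["ref_count"] + table["alt_count"]).to_numpy(dtype=float)
    af = np.asarray(table["alt_count"], dtype=float)[total > 0] / total[total > 0]
    counts, edges = np.histogram(af, bins=bins, range=(0.0, 1.0))
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "frequency": freq})


def histogram_modes(hist: pd.DataFrame) -> List[float]:
    """Bin centers of local maxima (strictly above both neighbors, ends allowed)."""
    f = hist["frequency"].to_numpy()
    centers = ((hist["bin_left"] + hist["bin_right"]) / 2).to_numpy()
    modes = []
    for i in range(len(f)):
        left = f[i - 1] if i > 0 else -np.inf
        right = f[i + 1] if i < len(f) - 1 else -np.inf
        if f[i] > left and f[i] > right and f[i] > 0:
            modes.append(float(centers[i]))
    return modes
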