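"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
fixed-effect IVW center; the Egger intercept tests directional pleiotropy;
leave-one-out quantifies single-SNP influence; and a PRESSO-style
(pleiotropy residual sum and outlier) test detects gross per-SNP pleiotropy
by comparing observed leave-one-out residuals against a parametric null.

Simulation-based p-values use add-one smoothing (count+1)/(n_sim+1) and are
therefore never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import InsufficientInstrumentsError
from .estimators import EggerEstimator, _ratios, ivw


@dataclass
class QResult:
    """Cochran's Q heterogeneity test: Q = sum of per-SNP contributions."""

    q: float
    df: int
    pval: float
    per_snp: pd.DataFrame  # columns snp_id, q_j

    @property
    def contributions(self) -> np.ndarray:
        return self.per_snp["q_j"].to_numpy(float)


@dataclass
class EggerInterceptResult:
    intercept: float
    se: float
    pval: float
    flags: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.intercept, self.se, self.pval))


@dataclass
class LooTable:
    """Leave-one-out IVW fits: one row per omitted SNP plus the all-SNP row."""

    df: pd.DataFrame  # columns snp_id, beta, se, pval; snp_id "ALL" for the full fit

    @property
    def all_snp_row(self) -> pd.Series:
        return self.df.loc[self.df["snp_id"] == "ALL"].iloc[0]


@dataclass
class PressoReport:
    rss_obs: float
    global_pval: float
    outlier_pvals: pd.DataFrame  # columns snp_id, pval_raw, pval_bonferroni
    outlier_ids: list[str]
    distortion_pval: float
    beta_before: float
    beta_after: float
    n_sim: int
    seed: int


def _weights(H):
    r, sr = _ratios(H)
    return r, sr, 1.0 / sr**2


def cochran_q(H) -> QResult:
    """Heterogeneity of the Wald ratios around the fixed-effect IVW estimate."""
    r, sr, w = _weights(H)
    k = len(r)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs k >= 2")
    center = float(np.sum(w * r) / np.sum(w))
    q_j = w * (r - center) ** 2
    q = float(np.sum(q_j))
    pval = float(chi2.sf(q, k - 1))
    snp_ids = H.snp_ids if hasattr(H, "snp_ids") else list(map(str, range(k)))
    return QResult(
        q=q,
        df=k - 1,
        pval=pval,
        per_snp=pd.DataFrame({"snp_id": snp_ids, "q_j": q_j}),
    )


def egger_intercept_test(H) -> EggerInterceptResult:
    """Directional-pleiotropy test: the MR-Egger intercept and its p-value."""
    est = EggerEstimator().fit(H)
    flags = list(est.result_.extra.get("flags", []))
    return EggerInterceptResult(
        intercept=est.intercept_,
        se=est.intercept_se_,
        pval=est.intercept_pval_,
        flags=flags,
    )


def leave_one_out(H, model: str = "random_multiplicative") -> LooTable:
    """Recompute IVW k times, omitting one SNP each time."""
    k = H.k if hasattr(H, "k") else len(H)
    if k < 2:
        raise InsufficientInstrumentsError("leave-one-out needs k >= 2")
    df = H.df if hasattr(H, "df") else H
    rows = []
    for i in range(k):
        sub = df.drop(df.index[i])
        res = ivw(sub, model=model)
        rows.append((df.iloc[i]["snp_id"], res.beta, res.se, res.pval))
    full = ivw(df, model=model)
    rows.append(("ALL", full.beta, full.se, full.pval))
    return LooTable(df=pd.DataFrame(rows, columns=["snp_id", "beta", "se", "pval"]))


def _loo_betas(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized fixed-effect IVW estimates leaving out each SNP in turn."""
    sw, swr = np.sum(w), np.sum(w * r)
    return (swr - w * r) / (sw - w)


def presso(H, n_sim: int = 1000, sig: float = 0.05, seed: int | None = None) -> PressoReport:
    """PRESSO-style global heterogeneity, per-SNP outlier and distortion tests.

    The observed residual sum of squares is sum_j w_j·(r_j − beta_loo(j))²;
    its null distribution comes from ``n_sim`` parametric simulations of the
    ratios around their leave-one-out fits. Per-SNP outlier p-values are the
    simulation tail probabilities of each SNP's contribution, Bonferroni
    corrected by k; SNPs below ``sig`` are outliers. The distortion test
    compares the post-removal estimate against removal of random same-size
    SNP subsets.
    """
    if seed is None:
        raise ValueError("seed is required for the simulation-based test")
    r, sr, w = _weights(H)
    k = len(r)
    if k < 4:
        raise InsufficientInstrumentsError("insufficient instruments for PRESSO (k >= 4)")
    snp_ids = H.snp_ids if hasattr(H, "snp_ids") else list(map(str, range(k)))

    loo = _loo_betas(r, w)
    q_obs = w * (r - loo) ** 2
    rss_obs = float(np.sum(q_obs))

    rng = np.random.default_rng(seed)
    r_sim = loo[None, :] + sr[None, :] * rng.standard_normal((n_sim, k))
    sw = np.sum(w)
    swr_sim = r_sim @ w
    loo_sim = (swr_sim[:, None] - w[None, :] * r_sim) / (sw - w[None, :])
    q_sim = w[None, :] * (r_sim - loo_sim) ** 2
    rss_sim = q_sim.sum(axis=1)

    global_pval = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    p_raw = (np.sum(q_sim >= q_obs[None, :], axis=0) + 1.0) / (n_sim + 1.0)
    p_bonf = np.minimum(1.0, k * p_raw)
    outlier_mask = p_bonf < sig
    outlier_ids = [s for s, m in zip(snp_ids, outlier_mask) if m]

    beta_before = float(np.sum(w * r) / sw)
    if outlier_ids and not outlier_mask.all():
        keep = ~outlier_mask
        beta_after = float(np.sum(w[keep] * r[keep]) / np.sum(w[keep]))
        m_out = int(outlier_mask.sum())
        d_obs = beta_after - beta_before
        d_sim = np.empty(n_sim)
        idx = np.arange(k)
        for b in range(n_sim):
            drop = rng.choice(idx, size=m_out, replace=False)
            mask = np.ones(k, dtype=bool)
            mask[drop] = False
            d_sim[b] = np.sum(w[mask] * r[mask]) / np.sum(w[mask]) - beta_before
        lo = (np.sum(d_sim <= d_obs) + 1.0) / (n_sim + 1.0)
        hi = (np.sum(d_sim >= d_obs) + 1.0) / (n_sim + 1.0)
        distortion_pval = min(1.0, 2.0 * min(lo, hi))
    else:
        beta_after = beta_before if not outlier_ids else float("nan")
        distortion_pval = float("nan")

    return PressoReport(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals=pd.DataFrame(
            {"snp_id": snp_ids, "pval_raw": p_raw, "pval_bonferroni": p_bonf}
        ),
        outlier_ids=outlier_ids,
        distortion_pval=float(distortion_pval),
        beta_before=beta_before,
        beta_after=beta_after,
        n_sim=n_sim,
        seed=seed,
    )
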