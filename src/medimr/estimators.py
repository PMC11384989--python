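"""The five causal-effect estimators and effect-scale conversions.

Each estimator is a scikit-learn-style class: construct with hyperparameters,
``fit`` on a harmonized exposure/outcome set (a :class:`~medimr.gwas_data.
HarmonizedSet` or a DataFrame with beta_exp/se_exp/beta_out/se_out columns),
then read fitted attributes ``beta_``, ``se_``, ``pval_``, ``k_`` and the
assembled ``result_``. Thin module-level functions (:func:`ivw`, ...) wrap
the classes for pipeline use.

All estimators operate on per-SNP Wald ratios r_j = beta_out/beta_exp with
first-order delta-method standard errors se_out/|beta_exp| (the conventional
no-measurement-error approximation; a second-order option adds the exposure
uncertainty). p-values use the normal reference by default, configurable
to t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._stats import Z95, two_sided_normal_p, two_sided_t_p
from .errors import InsufficientInstrumentsError, NoInstrumentsError
from .gwas_data import HarmonizedSet

METHOD_NAMES = ["IVW", "Egger", "WeightedMedian", "SimpleMode", "WeightedMode"]


@dataclass
class MrResult:
    """One estimator's causal estimate on the log-odds scale."""

    method: str
    k: int
    beta: float
    se: float
    pval: float
    or_point: float
    or_low: float
    or_high: float
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_beta_se(cls, method: str, k: int, beta: float, se: float, pval: float, extra=None):
        orp, orl, orh = beta_to_or(beta, se)
        return cls(
            method=method,
            k=k,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            or_point=orp,
            or_low=orl,
            or_high=orh,
            extra=dict(extra or {}),
        )


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Convert a log-odds estimate and SE to an odds ratio with 95% CI."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return (
        math.exp(beta),
        math.exp(beta - Z95 * se),
        math.exp(beta + Z95 * se),
    )


def wald_ratio(
    beta_exp: float,
    beta_out: float,
    se_out: float,
    se_exp: float | None = None,
    second_order: bool = False,
) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp and its delta-method SE."""
    if beta_exp == 0:
        raise ValueError("wald ratio undefined for beta_exp = 0")
    ratio = beta_out / beta_exp
    var = (se_out / beta_exp) ** 2
    if second_order:
        if se_exp is None:
            raise ValueError("second-order SE requires se_exp")
        var += (beta_out * se_exp / beta_exp**2) ** 2
    return ratio, math.sqrt(var)


def _extract(H) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(H, HarmonizedSet):
        be, se_e, bo, se_o = H.arrays()
    elif isinstance(H, pd.DataFrame):
        for col in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if col not in H.columns:
                raise ValueError(f"harmonized table missing column {col!r}")
        be = H["beta_exp"].to_numpy(float)
        se_e = H["se_exp"].to_numpy(float)
        bo = H["beta_out"].to_numpy(float)
        se_o = H["se_out"].to_numpy(float)
    else:
        raise TypeError("expected a HarmonizedSet or a DataFrame")
    if np.any(~np.isfinite(be)) or np.any(~np.isfinite(bo)):
        raise ValueError("non-finite effect sizes in harmonized data")
    if np.any(se_o <= 0) or np.any(se_e <= 0):
        raise ValueError("standard errors must be positive")
    if np.any(be == 0):
        raise ValueError("beta_exp = 0: Wald ratio undefined; drop the SNP upstream")
    return be, se_e, bo, se_o


def _ratios(H, second_order: bool = False):
    be, se_e, bo, se_o = _extract(H)
    r = bo / be
    var = (se_o / be) ** 2
    if second_order:
        var += (bo * se_e / be**2) ** 2
    return r, np.sqrt(var)


def _pval(z: float, df_mode: str, df: int) -> float:
    if df_mode == "t":
        return float(two_sided_t_p(z, max(df, 1)))
    return float(two_sided_normal_p(z))


class IVWEstimator(BaseEstimator):
    """Inverse-variance weighted estimator (the primary MR method).

    Pools Wald ratios with weights 1/ratio_se², equivalently weighted least
    squares of beta_out on beta_exp through the origin with weights 1/se_out².
    ``model="random_multiplicative"`` (default) inflates the fixed-effect SE
    by max(1, sqrt(Q/(k−1))) so heterogeneity never shrinks it.
    """

    def __init__(self, model: str = "random_multiplicative", df_mode: str = "normal"):
        self.model = model
        self.df_mode = df_mode

    def fit(self, H, y=None):
        if self.model not in ("fixed", "random_multiplicative"):
            raise ValueError(f"unknown IVW model {self.model!r}")
        r, sr = _ratios(H)
        k = len(r)
        if k == 0:
            raise NoInstrumentsError("no instruments")
        w = 1.0 / sr**2
        beta = float(np.sum(w * r) / np.sum(w))
        se_fixed = float(np.sqrt(1.0 / np.sum(w)))
        q = float(np.sum(w * (r - beta) ** 2))
        scale = 1.0
        if self.model == "random_multiplicative" and k >= 2:
            scale = max(1.0, math.sqrt(q / (k - 1)))
        se = se_fixed * scale
        self.k_ = k
        self.beta_ = beta
        self.se_ = se
        self.pval_ = _pval(beta / se, self.df_mode, k - 1)
        self.q_ = q
        self.scale_ = scale
        self.result_ = MrResult.from_beta_se(
            "IVW", k, beta, se, self.pval_,
            extra={"model": self.model, "cochran_q": q, "re_scale": scale},
        )
        return self


class EggerEstimator(BaseEstimator):
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Rows are flipped so beta_exp >= 0 before fitting (required for the
    intercept to measure directional pleiotropy). The slope is the causal
    estimate under the InSIDE assumption; the intercept, its SE and p-value
    are exposed as ``intercept_``/``intercept_se_``/``intercept_pval_``.
    SEs use a multiplicative random-effects scale max(1, sigma).
    """

    #: residual-variance floor below which the fit is flagged degenerate
    _DEGENERATE_TOL = 1e-12

    def __init__(self, df_mode: str = "normal"):
        self.df_mode = df_mode

    def fit(self, H, y=None):
        be, se_e, bo, se_o = _extract(H)
        k = len(be)
        if k < 3:
            raise InsufficientInstrumentsError("insufficient instruments for Egger (k >= 3)")
        sign = np.where(be < 0, -1.0, 1.0)
        x = be * sign
        yv = bo * sign
        w = 1.0 / se_o**2
        X = np.column_stack([np.ones(k), x])
        xtwx = X.T @ (w[:, None] * X)
        xtwy = X.T @ (w * yv)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = yv - X @ coef
        rss_w = float(np.sum(w * resid**2))
        sigma2 = rss_w / (k - 2)
        cov_unit = np.linalg.inv(xtwx)
        self.k_ = k
        self.intercept_ = float(coef[0])
        self.beta_ = float(coef[1])
        self.sigma2_ = sigma2
        if sigma2 < self._DEGENERATE_TOL:
            # exact fit: zero residual variance, no sampling-based inference
            self.se_ = 0.0
            self.intercept_se_ = 0.0
            self.pval_ = float("nan")
            self.intercept_pval_ = float("nan")
            flags = ["degenerate_fit"]
        else:
            cov = cov_unit * max(1.0, sigma2)
            self.se_ = float(np.sqrt(cov[1, 1]))
            self.intercept_se_ = float(np.sqrt(cov[0, 0]))
            self.pval_ = _pval(self.beta_ / self.se_, self.df_mode, k - 2)
            self.intercept_pval_ = _pval(
                self.intercept_ / self.intercept_se_, self.df_mode, k - 2
            )
            flags = []
        self.result_ = MrResult.from_beta_se(
            "Egger", k, self.beta_, self.se_, self.pval_,
            extra={
                "intercept": self.intercept_,
                "intercept_se": self.intercept_se_,
                "intercept_pval": self.intercept_pval_,
                "sigma2": sigma2,
                "flags": flags,
            },
        )
        return self


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="mergesort")
    r_s = r[order]
    w_s = w[order]
    p = (np.cumsum(w_s) - 0.5 * w_s) / np.sum(w_s)
    return float(np.interp(0.5, p, r_s))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median estimator: consistent when >=50% of weight is valid.

    The estimate is the Wald ratio at which the cumulative normalized
    inverse-variance weight crosses 0.5, with linear interpolation between
    bracketing ratios. SE by seeded parametric bootstrap.
    """

    def __init__(self, n_boot: int = 1000, seed: int | None = None, df_mode: str = "normal"):
        self.n_boot = n_boot
        self.seed = seed
        self.df_mode = df_mode

    def fit(self, H, y=None):
        r, sr = _ratios(H)
        k = len(r)
        if k < 3:
            raise InsufficientInstrumentsError("insufficient instruments (k >= 3)")
        if self.seed is None:
            raise ValueError("seed is required for the bootstrap SE")
        # canonical ordering makes the bootstrap draw assignment, and hence
        # the SE, invariant to the row order of the input
        order = np.lexsort((sr, r))
        r, sr = r[order], sr[order]
        w = 1.0 / sr**2
        beta = _weighted_median(r, w)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            boots[b] = _weighted_median(r + sr * rng.standard_normal(k), w)
        se = float(np.std(boots, ddof=1))
        self.k_ = k
        self.beta_ = beta
        self.se_ = se
        self.pval_ = _pval(beta / se, self.df_mode, k - 1) if se > 0 else float("nan")
        self.result_ = MrResult.from_beta_se(
            "WeightedMedian", k, beta, se, self.pval_, extra={"n_boot": self.n_boot}
        )
        return self


def _kde_mode(r: np.ndarray, w: np.ndarray, phi: float, grid_size: int = 512) -> float:
    """Mode of a weighted Gaussian KDE over the ratios.

    Bandwidth: phi · 0.9 · min(sd, 1.4826·mad) · k^(−1/5) (modified Silverman).
    Degenerate spread falls back to the ratio carrying the most weight.
    """
    k = len(r)
    mad = np.median(np.abs(r - np.median(r)))
    spread = min(np.std(r, ddof=1) if k > 1 else 0.0, 1.4826 * mad)
    if spread <= 0:
        uniq, inv = np.unique(r, return_inverse=True)
        mass = np.bincount(inv, weights=w)
        return float(uniq[np.argmax(mass)])
    h = phi * 0.9 * spread * k ** (-1.0 / 5.0)
    grid = np.linspace(r.min(), r.max(), grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


class ModeEstimator(BaseEstimator):
    """Simple-mode / weighted-mode estimator (plurality-valid assumption).

    The estimate is the kernel-density mode of the Wald ratios, unweighted
    (simple) or inverse-variance weighted. SE by seeded parametric bootstrap.
    """

    def __init__(
        self,
        weighted: bool = False,
        bandwidth_phi: float = 1.0,
        n_boot: int = 1000,
        seed: int | None = None,
        df_mode: str = "normal",
    ):
        self.weighted = weighted
        self.bandwidth_phi = bandwidth_phi
        self.n_boot = n_boot
        self.seed = seed
        self.df_mode = df_mode

    def fit(self, H, y=None):
        r, sr = _ratios(H)
        k = len(r)
        if k < 3:
            raise InsufficientInstrumentsError("insufficient instruments (k >= 3)")
        if self.seed is None:
            raise ValueError("seed is required for the bootstrap SE")
        order = np.lexsort((sr, r))  # row-order invariance, as in the median
        r, sr = r[order], sr[order]
        w = 1.0 / sr**2 if self.weighted else np.ones(k)
        beta = _kde_mode(r, w, self.bandwidth_phi)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            boots[b] = _kde_mode(r + sr * rng.standard_normal(k), w, self.bandwidth_phi)
        se = float(np.std(boots, ddof=1))
        name = "WeightedMode" if self.weighted else "SimpleMode"
        self.k_ = k
        self.beta_ = beta
        self.se_ = se
        self.pval_ = _pval(beta / se, self.df_mode, k - 1) if se > 0 else float("nan")
        self.result_ = MrResult.from_beta_se(
            name, k, beta, se, self.pval_,
            extra={"n_boot": self.n_boot, "bandwidth_phi": self.bandwidth_phi},
        )
        return self


def ivw(H, model: str = "random_multiplicative") -> MrResult:
    return IVWEstimator(model=model).fit(H).result_


def egger(H) -> MrResult:
    return EggerEstimator().fit(H).result_


def weighted_median(H, n_boot: int = 1000, seed: int | None = None) -> MrResult:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(H).result_


def mode_estimators(
    H,
    weighted: bool = False,
    bandwidth_phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    return ModeEstimator(
        weighted=weighted, bandwidth_phi=bandwidth_phi, n_boot=n_boot, seed=seed
    ).fit(H).result_


def run_all_methods(
    H,
    seed: int,
    n_boot: int = 1000,
    ivw_model: str = "random_multiplicative",
) -> dict[str, MrResult | None]:
    """Run the five-method battery; methods needing more SNPs yield None."""
    out: dict[str, MrResult | None] = {}
    out["IVW"] = ivw(H, model=ivw_model)
    for name, fn in (
        ("Egger", lambda: egger(H)),
        ("WeightedMedian", lambda: weighted_median(H, n_boot=n_boot, seed=seed)),
        ("SimpleMode", lambda: mode_estimators(H, weighted=False, n_boot=n_boot, seed=seed + 1)),
        ("WeightedMode", lambda: mode_estimators(H, weighted=True, n_boot=n_boot, seed=seed + 2)),
    ):
        try:
            out[name] = fn()
        except InsufficientInstrumentsError:
            out[name] = None
    return out
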