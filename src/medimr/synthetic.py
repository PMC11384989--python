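"""Synthetic GWAS summary statistics with known ground truth.

Summary statistics are simulated directly on the beta/SE scale (no
individual-level genotypes): per-SNP standard errors use the standard
``1/sqrt(2·maf·(1−maf)·n)`` approximation for a standardized trait, and
observed effects are the true marginal effects plus Gaussian noise, with
noise correlated inside LD blocks. Three studies share one SNP panel:

* exposure: instruments carry effects ``gamma_j``;
* mediator: ``beta1·gamma_j`` plus mediator-specific effects ``delta_j``;
* outcome: ``(theta + beta1·beta2)·gamma_j + beta2·delta_j + eta_j + alpha_j``
  where ``alpha_j`` are pleiotropic direct effects and ``eta_j`` are
  outcome-specific instrument effects (for reverse-MR scenarios).

The total exposure→outcome effect is therefore ``theta + beta1·beta2``
(``theta`` is the direct effect), conserving the mediation identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._stats import two_sided_normal_p
from .gwas_data import STANDARD_FIELDS, SummaryStudy

# allele pairs with rough transition/transversion weighting; palindromic
# pairs (A/T, C/G) kept at ~10% so the ambiguity rule is exercised
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]
_ALLELE_PAIR_P = [0.35, 0.35, 0.10, 0.10, 0.05, 0.05]

_SPACING_BP = 100_000  # SNP spacing on the synthetic chromosome


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated three-study MR scenario.

    theta is the *direct* exposure→outcome effect; the implied total effect
    is ``theta + beta1·beta2``. ``gamma_sd`` scales instrument strength: with
    the default exposure sample size the typical instrument |z| is ~7, so the
    strongest instruments comfortably clear the p < 1e-5 selection threshold.
    """

    n_instruments: int = 50
    n_null_snps: int = 200
    n_mediator_instruments: int = 0
    n_outcome_instruments: int = 0
    n_exposure: int = 20_000
    n_outcome: int = 315_000
    n_mediator: int = 20_000
    theta: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_effect: float | None = None  # default 10·pleiotropy_sd, else 0.1
    outlier_sign: str = "random"  # random | positive | negative
    gamma_sd: float = 0.08
    gamma_sign: str = "symmetric"  # symmetric | positive
    ld_block_size: int = 1
    ld_r: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_instruments,
            self.n_null_snps,
            self.n_mediator_instruments,
            self.n_outcome_instruments,
            self.n_outliers,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all SNP counts must be >= 0")
        if min(self.n_exposure, self.n_outcome, self.n_mediator) <= 2:
            raise ValueError("sample sizes must be > 2")
        if not abs(self.ld_r) < 1:
            raise ValueError("|ld_r| must be < 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.gamma_sign not in ("symmetric", "positive"):
            raise ValueError(f"unknown gamma_sign {self.gamma_sign!r}")
        if self.outlier_sign not in ("random", "positive", "negative"):
            raise ValueError(f"unknown outlier_sign {self.outlier_sign!r}")
        if self.n_outliers > self.n_instruments:
            raise ValueError("n_outliers cannot exceed n_instruments")

    @property
    def n_snps(self) -> int:
        return (
            self.n_instruments
            + self.n_mediator_instruments
            + self.n_outcome_instruments
            + self.n_null_snps
        )


@dataclass
class SyntheticTruth:
    """Planted parameters a simulation must let tests recover."""

    config: SimulationConfig
    snp_ids: list[str]
    gamma: np.ndarray  # exposure instrument effects (0 for non-instruments)
    delta: np.ndarray  # mediator-specific effects
    eta: np.ndarray  # outcome-specific effects
    alpha: np.ndarray  # pleiotropic direct effects on the outcome
    outlier_ids: list[str] = field(default_factory=list)

    @property
    def total_effect(self) -> float:
        """Implied total exposure→outcome effect: theta + beta1·beta2."""
        c = self.config
        return c.theta + c.beta1 * c.beta2

    @property
    def instrument_ids(self) -> list[str]:
        return [s for s, g in zip(self.snp_ids, self.gamma) if g != 0.0]

    @property
    def mediator_instrument_ids(self) -> list[str]:
        return [s for s, d in zip(self.snp_ids, self.delta) if d != 0.0]

    @property
    def outcome_instrument_ids(self) -> list[str]:
        return [s for s, e in zip(self.snp_ids, self.eta) if e != 0.0]

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "snp_ids": self.snp_ids,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "eta": self.eta.tolist(),
            "alpha": self.alpha.tolist(),
            "outlier_ids": self.outlier_ids,
            "total_effect": self.total_effect,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


class SimulatedStudies(NamedTuple):
    exposure: SummaryStudy
    outcome: SummaryStudy
    mediator: SummaryStudy
    truth: SyntheticTruth


def _block_slices(m: int, block: int):
    for start in range(0, m, block):
        yield slice(start, min(start + block, m))


def _ld_smear(x: np.ndarray, block: int, r: float) -> np.ndarray:
    """Marginal effects implied by equicorrelation-r LD blocks: R @ x per block."""
    if block <= 1 or r == 0.0:
        return x
    out = np.empty_like(x)
    for sl in _block_slices(len(x), block):
        xs = x[sl]
        out[sl] = (1.0 - r) * xs + r * xs.sum()
    return out


def _correlated_noise(rng, se: np.ndarray, block: int, r: float) -> np.ndarray:
    """Zero-mean noise with per-SNP scale ``se`` and equicorrelation-r blocks."""
    z = rng.standard_normal(len(se))
    if block <= 1 or r == 0.0:
        return se * z
    out = np.empty_like(se)
    # equicorrelation factorization: sqrt(r)·(shared) + sqrt(1-r)·(idiosyncratic)
    if r >= 0:
        a, b = np.sqrt(r), np.sqrt(1.0 - r)
        for sl in _block_slices(len(se), block):
            shared = rng.standard_normal()
            out[sl] = a * shared + b * z[sl]
    else:
        # negative equicorrelation: fall back to per-block Cholesky
        for sl in _block_slices(len(se), block):
            m = sl.stop - sl.start
            cov = np.full((m, m), r)
            np.fill_diagonal(cov, 1.0)
            out[sl] = np.linalg.cholesky(cov) @ z[sl]
    return out * se


def _study_frame(
    snp_ids, pos, ea, oa, eaf, beta, se, n
) -> pd.DataFrame:
    pval = two_sided_normal_p(beta / se)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
            "pval_derived": True,
        }
    )
    return df[STANDARD_FIELDS + ["pval_derived"]]


def simulate_mr_study(config: SimulationConfig) -> SimulatedStudies:
    """Simulate exposure, outcome and mediator studies sharing one SNP panel.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    snp_ids = [f"rs{i + 1:07d}" for i in range(m)]
    pos = 1 + np.arange(m, dtype=np.int64) * _SPACING_BP
    pair_idx = rng.choice(len(_ALLELE_PAIRS), size=m, p=_ALLELE_PAIR_P)
    flip = rng.random(m) < 0.5
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    ea, oa = np.where(flip, oa, ea), np.where(flip, ea, oa)
    eaf = rng.uniform(*config.eaf_range, size=m)

    n_i, n_mi, n_oi = (
        config.n_instruments,
        config.n_mediator_instruments,
        config.n_outcome_instruments,
    )
    gamma = np.zeros(m)
    delta = np.zeros(m)
    eta = np.zeros(m)
    gamma[:n_i] = rng.normal(0.0, config.gamma_sd, size=n_i)
    if config.gamma_sign == "positive":
        gamma[:n_i] = np.abs(gamma[:n_i])
    delta[n_i : n_i + n_mi] = rng.normal(0.0, config.gamma_sd, size=n_mi)
    eta[n_i + n_mi : n_i + n_mi + n_oi] = rng.normal(0.0, config.gamma_sd, size=n_oi)

    alpha = np.zeros(m)
    if config.pleiotropy_mode == "balanced":
        alpha[:n_i] = rng.normal(0.0, config.pleiotropy_sd, size=n_i)
    elif config.pleiotropy_mode == "directional":
        # directional relative to the exposure-increasing allele: a constant
        # mean on arbitrarily labelled alleles would cancel under the
        # orientation convention and be undetectable by design
        alpha[:n_i] = np.where(gamma[:n_i] < 0, -1.0, 1.0) * rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=n_i
        )

    outlier_ids: list[str] = []
    if config.n_outliers:
        effect = config.outlier_effect
        if effect is None:
            effect = 10.0 * config.pleiotropy_sd if config.pleiotropy_sd > 0 else 0.1
        which = rng.choice(n_i, size=config.n_outliers, replace=False)
        if config.outlier_sign == "random":
            signs = rng.choice([-1.0, 1.0], size=config.n_outliers)
        else:
            signs = np.full(config.n_outliers, 1.0 if config.outlier_sign == "positive" else -1.0)
        alpha[which] += signs * effect
        outlier_ids = sorted(snp_ids[j] for j in which)

    theta_total = config.theta + config.beta1 * config.beta2
    true_exp = gamma
    true_med = config.beta1 * gamma + delta
    true_out = theta_total * gamma + config.beta2 * delta + eta + alpha

    block, r = config.ld_block_size, config.ld_r
    var_term = 2.0 * eaf * (1.0 - eaf)
    se_exp = 1.0 / np.sqrt(var_term * config.n_exposure)
    se_out = 1.0 / np.sqrt(var_term * config.n_outcome)
    se_med = 1.0 / np.sqrt(var_term * config.n_mediator)

    beta_exp = _ld_smear(true_exp, block, r) + _correlated_noise(rng, se_exp, block, r)
    beta_out = _ld_smear(true_out, block, r) + _correlated_noise(rng, se_out, block, r)
    beta_med = _ld_smear(true_med, block, r) + _correlated_noise(rng, se_med, block, r)

    exposure = SummaryStudy(
        study_id="sim_exposure",
        trait_name="simulated exposure",
        df=_study_frame(snp_ids, pos, ea, oa, eaf, beta_exp, se_exp, config.n_exposure),
        trait_type="quantitative",
        default_n=float(config.n_exposure),
    )
    outcome = SummaryStudy(
        study_id="sim_outcome",
        trait_name="simulated outcome",
        df=_study_frame(snp_ids, pos, ea, oa, eaf, beta_out, se_out, config.n_outcome),
        trait_type="binary",
        default_n=float(config.n_outcome),
    )
    mediator = SummaryStudy(
        study_id="sim_mediator",
        trait_name="simulated mediator",
        df=_study_frame(snp_ids, pos, ea, oa, eaf, beta_med, se_med, config.n_mediator),
        trait_type="quantitative",
        default_n=float(config.n_mediator),
    )
    truth = SyntheticTruth(
        config=config,
        snp_ids=snp_ids,
        gamma=gamma,
        delta=delta,
        eta=eta,
        alpha=alpha,
        outlier_ids=outlier_ids,
    )
    return SimulatedStudies(exposure, outcome, mediator, truth)


def ld_matrix(truth: SyntheticTruth) -> pd.DataFrame:
    """Block-diagonal LD correlation matrix implied by the simulation config."""
    c = truth.config
    m = len(truth.snp_ids)
    mat = np.eye(m)
    if c.ld_block_size > 1 and c.ld_r != 0.0:
        for sl in _block_slices(m, c.ld_block_size):
            blk = np.full((sl.stop - sl.start,) * 2, c.ld_r)
            np.fill_diagonal(blk, 1.0)
            mat[sl, sl] = blk
    return pd.DataFrame(mat, index=truth.snp_ids, columns=truth.snp_ids)


def simulate_screen(
    n_exposures: int,
    causal_thetas: dict[int, float],
    n_instruments: int = 30,
    n_null_snps: int = 50,
    n_exposure: int = 20_000,
    n_outcome: int = 315_000,
    gamma_sd: float = 0.08,
    seed: int = 0,
) -> tuple[list[SummaryStudy], SummaryStudy, pd.DataFrame, dict]:
    """Simulate a many-exposure screen against one outcome.

    Each exposure owns a disjoint slice of ``n_instruments`` instrument SNPs
    on a shared panel; ``causal_thetas`` maps exposure index -> true effect
    (missing indices are null). Returns (exposures, outcome, ld, truth_dict);
    the LD matrix is the identity (independent SNPs).
    """
    rng = np.random.default_rng(seed)
    m = n_exposures * n_instruments + n_null_snps
    snp_ids = [f"rs{i + 1:07d}" for i in range(m)]
    pos = 1 + np.arange(m, dtype=np.int64) * _SPACING_BP
    pair_idx = rng.choice(len(_ALLELE_PAIRS), size=m, p=_ALLELE_PAIR_P)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    eaf = rng.uniform(0.05, 0.95, size=m)
    var_term = 2.0 * eaf * (1.0 - eaf)
    se_exp = 1.0 / np.sqrt(var_term * n_exposure)
    se_out = 1.0 / np.sqrt(var_term * n_outcome)

    gammas = np.zeros((n_exposures, m))
    for e in range(n_exposures):
        sl = slice(e * n_instruments, (e + 1) * n_instruments)
        gammas[e, sl] = rng.normal(0.0, gamma_sd, size=n_instruments)

    exposures = []
    for e in range(n_exposures):
        beta = gammas[e] + rng.standard_normal(m) * se_exp
        exposures.append(
            SummaryStudy(
                study_id=f"exposure_{e:03d}",
                trait_name=f"simulated exposure {e}",
                df=_study_frame(snp_ids, pos, ea, oa, eaf, beta, se_exp, n_exposure),
                default_n=float(n_exposure),
            )
        )

    true_out = np.zeros(m)
    for e, theta in causal_thetas.items():
        true_out += theta * gammas[e]
    beta_out = true_out + rng.standard_normal(m) * se_out
    outcome = SummaryStudy(
        study_id="sim_outcome",
        trait_name="simulated outcome",
        df=_study_frame(snp_ids, pos, ea, oa, eaf, beta_out, se_out, n_outcome),
        trait_type="binary",
        default_n=float(n_outcome),
    )
    ld = pd.DataFrame(np.eye(m), index=snp_ids, columns=snp_ids)
    truth = {
        "causal_thetas": dict(causal_thetas),
        "instrument_ids": {
            e: snp_ids[e * n_instruments : (e + 1) * n_instruments]
            for e in range(n_exposures)
        },
    }
    return exposures, outcome, ld, truth
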