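"""Two-step mediation MR: decomposing an exposure→outcome effect.

The total effect alpha (exposure→outcome), the step effects beta1
(exposure→mediator) and beta2 (mediator→outcome, with mediator instruments
that associate with the exposure excluded), the indirect effect
beta3 = beta1·beta2, and the proportion mediated beta3/alpha. Inference for
beta3 is by parametric bootstrap of the summary statistics — the only
resampling available without individual-level data.

The exposure-adjustment step ("conditional on the exposure") is
operationalized as instrument exclusion: mediator instruments with exposure
p < 1e-5 are removed before the mediator→outcome leg. Multivariable MR is
out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import NoInstrumentsError
from .estimators import ivw
from .gwas_data import SummaryStudy, harmonize
from .instruments import InstrumentSet, select_instruments


@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition with bootstrap CI.

    proportion = beta3/alpha is reported untruncated; when beta3 and alpha
    disagree in sign the report is flagged ``opposite_sign_proportion``.
    """

    alpha: float
    alpha_se: float
    beta1: float
    beta1_se: float
    beta2: float
    beta2_se: float
    beta3: float
    proportion: float
    k_alpha: int
    k_beta1: int
    k_beta2: int
    boot_ci_low: float = float("nan")
    boot_ci_high: float = float("nan")
    boot_pval: float = float("nan")
    n_boot: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def exclude_exposure_snps(
    mediator_instruments: InstrumentSet,
    exposure: SummaryStudy,
    threshold: float = 1e-5,
) -> InstrumentSet:
    """Remove mediator instruments associated with the exposure (p < threshold).

    Instruments absent from the exposure study are retained with a warning —
    absence of evidence is not treated as exposure association.
    """
    kept: list[str] = []
    exclusions = list(mediator_instruments.exclusions)
    for snp in mediator_instruments.snp_ids:
        if snp not in exposure:
            warnings.warn(
                f"{snp}: not in exposure study, retained without exposure-association check",
                stacklevel=2,
            )
            kept.append(snp)
            continue
        if exposure.get(snp).pval < threshold:
            exclusions.append((snp, "exposure_assoc", f"exposure pval < {threshold:g}"))
        else:
            kept.append(snp)
    table = mediator_instruments.table
    table = table[table["snp_id"].isin(kept)].reset_index(drop=True)
    return InstrumentSet(
        exposure_id=mediator_instruments.exposure_id,
        snp_ids=kept,
        table=table,
        exclusions=exclusions,
    )


def _mr_leg(exp_study, out_study, ld, config: PipelineConfig, instruments=None):
    """Select instruments (unless given), harmonize and fit IVW for one leg."""
    if instruments is None:
        instruments = select_instruments(
            exp_study,
            ld,
            pval_threshold=config.pval_threshold,
            window_kb=config.window_kb,
            r2_max=config.r2_max,
            f_min=config.f_min,
        )
    if not instruments.snp_ids:
        raise NoInstrumentsError(
            f"no instruments for {exp_study.study_id} -> {out_study.study_id}"
        )
    H = harmonize(
        exp_study,
        out_study,
        instruments.snp_ids,
        palindromic_maf_threshold=config.palindromic_maf,
    )
    if H.k == 0:
        raise NoInstrumentsError(
            f"no instruments survived harmonization for "
            f"{exp_study.study_id} -> {out_study.study_id}"
        )
    return H, instruments, ivw(H, model=config.ivw_model)


def two_step_mediation(
    exposure: SummaryStudy,
    mediator: SummaryStudy,
    outcome: SummaryStudy,
    ld,
    config: PipelineConfig | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """Estimate alpha, beta1, beta2, beta3 = beta1·beta2 and the proportion mediated.

    With ``n_boot`` > 0 a parametric bootstrap fills the CI and p-value for
    beta3 (see :func:`bootstrap_indirect`).
    """
    config = config or PipelineConfig()
    legs = _mediation_legs(exposure, mediator, outcome, ld, config)
    result = _assemble(legs, config)
    if n_boot > 0:
        ci_low, ci_high, pval = _bootstrap_from_legs(legs, config, n_boot, seed)
        result.boot_ci_low = ci_low
        result.boot_ci_high = ci_high
        result.boot_pval = pval
        result.n_boot = n_boot
        result.seed = seed
    return result


def _mediation_legs(exposure, mediator, outcome, ld, config):
    try:
        H_alpha, inst_exp, res_alpha = _mr_leg(exposure, outcome, ld, config)
    except NoInstrumentsError as exc:
        raise NoInstrumentsError(f"total-effect leg (exposure->outcome): {exc}") from exc
    try:
        H_b1, _, res_b1 = _mr_leg(exposure, mediator, ld, config, instruments=inst_exp)
    except NoInstrumentsError as exc:
        raise NoInstrumentsError(f"step-1 leg (exposure->mediator): {exc}") from exc
    try:
        inst_med = select_instruments(
            mediator,
            ld,
            pval_threshold=config.pval_threshold,
            window_kb=config.window_kb,
            r2_max=config.r2_max,
            f_min=config.f_min,
        )
        inst_med = exclude_exposure_snps(
            inst_med, exposure, threshold=config.mediator_exclusion_pval
        )
        H_b2, _, res_b2 = _mr_leg(mediator, outcome, ld, config, instruments=inst_med)
    except NoInstrumentsError as exc:
        raise NoInstrumentsError(f"step-2 leg (mediator->outcome): {exc}") from exc
    return {"alpha": (H_alpha, res_alpha), "beta1": (H_b1, res_b1), "beta2": (H_b2, res_b2)}


def _assemble(legs, config) -> MediationResult:
    res_alpha = legs["alpha"][1]
    res_b1 = legs["beta1"][1]
    res_b2 = legs["beta2"][1]
    beta3 = res_b1.beta * res_b2.beta
    flags: list[str] = []
    if res_alpha.beta != 0:
        proportion = beta3 / res_alpha.beta
        if beta3 != 0 and np.sign(beta3) != np.sign(res_alpha.beta):
            flags.append("opposite_sign_proportion")
    else:
        proportion = float("nan")
        flags.append("zero_total_effect")
    return MediationResult(
        alpha=res_alpha.beta,
        alpha_se=res_alpha.se,
        beta1=res_b1.beta,
        beta1_se=res_b1.se,
        beta2=res_b2.beta,
        beta2_se=res_b2.se,
        beta3=beta3,
        proportion=proportion,
        k_alpha=res_alpha.k,
        k_beta1=res_b1.k,
        k_beta2=res_b2.k,
        flags=flags,
    )


def _leg_boot(H, model, rng, n_boot):
    """Bootstrap IVW estimates by resampling the outcome-side betas."""
    be = H.df["beta_exp"].to_numpy(float)
    bo = H.df["beta_out"].to_numpy(float)
    se_o = H.df["se_out"].to_numpy(float)
    w = 1.0 / se_o**2
    denom = np.sum(w * be**2)
    bo_star = bo[None, :] + se_o[None, :] * rng.standard_normal((n_boot, len(bo)))
    return (bo_star * (w * be)[None, :]).sum(axis=1) / denom


def _bootstrap_from_legs(legs, config, n_boot, seed):
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    if n_boot < 100:
        warnings.warn("unstable percentile CI: n_boot < 100", stacklevel=2)
    rng = np.random.default_rng(seed)
    b1_star = _leg_boot(legs["beta1"][0], config.ivw_model, rng, n_boot)
    b2_star = _leg_boot(legs["beta2"][0], config.ivw_model, rng, n_boot)
    b3_star = b1_star * b2_star
    ci_low, ci_high = np.percentile(b3_star, [2.5, 97.5])
    n_le = np.sum(b3_star <= 0) + 1.0
    n_ge = np.sum(b3_star >= 0) + 1.0
    pval = min(1.0, 2.0 * min(n_le, n_ge) / (n_boot + 1.0))
    return float(ci_low), float(ci_high), float(pval)


def bootstrap_indirect(
    exposure: SummaryStudy,
    mediator: SummaryStudy,
    outcome: SummaryStudy,
    ld,
    config: PipelineConfig | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI and p-value for the indirect effect beta3.

    Each leg's outcome-side betas are resampled from Normal(beta, se), the
    leg IVW estimates recomputed and beta3* = beta1*·beta2* formed per
    replicate. The p-value uses add-one smoothing, never exactly zero.
    """
    config = config or PipelineConfig()
    legs = _mediation_legs(exposure, mediator, outcome, ld, config)
    return _bootstrap_from_legs(legs, config, n_boot, seed)
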