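"""Many-exposure screening against one outcome, evidence tiers, reverse MR.

Each exposure runs the full pipeline (instrument selection, harmonization,
five estimators, sensitivity diagnostics) and is assigned an evidence tier
from method agreement at the 0.05 level:

* ``none`` — the primary (IVW) test is not significant;
* ``inclusion`` — only IVW is significant;
* ``strong`` — 2–3 of the five methods significant (IVW among them);
* ``very_strong`` — >=4 methods significant.

Benjamini–Hochberg q-values over the IVW p-values are reported across the
screen; tiering uses raw p-values by default (configurable). Failures of
individual exposures are contained: the screen always completes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import MedimrError, NoInstrumentsError
from .estimators import METHOD_NAMES, MrResult, run_all_methods
from .gwas_data import SummaryStudy
from .mediation import _mr_leg
from .sensitivity import cochran_q, egger_intercept_test, presso

TIERS = ("none", "inclusion", "strong", "very_strong")


def classify_tier(method_pvals, alpha_sig: float = 0.05) -> str:
    """Evidence tier from the five method p-values (IVW first).

    NA p-values count as non-significant. Any tier above ``none`` requires
    the primary IVW test itself to be significant.
    """
    pvals = list(method_pvals)
    if len(pvals) != 5:
        raise ValueError("exactly five method p-values expected (IVW first)")

    def sig(p) -> bool:
        return p is not None and not np.isnan(p) and p < alpha_sig

    if not sig(pvals[0]):
        return "none"
    c = sum(sig(p) for p in pvals)
    if c >= 4:
        return "very_strong"
    if c >= 2:
        return "strong"
    return "inclusion"


@dataclass
class ScreenRow:
    """One exposure's screen summary (flattened into the output table)."""

    exposure_id: str
    k: int
    results: dict[str, MrResult | None]
    q_pval: float
    egger_intercept_pval: float
    presso_global_pval: float
    reverse_pval: float
    tier: str
    n_methods_significant: int
    failure_reason: str = ""
    direction: str = ""


def _exposure_seed(base_seed: int, exposure_id: str) -> int:
    """Order-independent per-exposure seed below 2**31."""
    return (base_seed * 1_000_003 + zlib.crc32(exposure_id.encode())) % (2**31 - 1)


def reverse_mr(
    outcome_as_exposure: SummaryStudy,
    exposure_as_outcome: SummaryStudy,
    ld,
    config: PipelineConfig | None = None,
) -> MrResult:
    """Run the IVW pipeline with exposure and outcome roles swapped.

    Instruments are selected from the original outcome study at the reverse
    threshold; raises :class:`NoInstrumentsError` when the outcome has none
    (reported upstream as reverse-untestable rather than a failure).
    """
    config = config or PipelineConfig()
    rev = PipelineConfig(**{**config.to_dict(), "pval_threshold": config.reverse_pval_threshold})
    _, _, res = _mr_leg(outcome_as_exposure, exposure_as_outcome, ld, rev)
    return res


def _screen_one(exposure, outcome, ld, config, seed) -> ScreenRow:
    H, _, _ = _mr_leg(exposure, outcome, ld, config)
    results = run_all_methods(
        H, seed=seed, n_boot=config.n_boot, ivw_model=config.ivw_model
    )
    q_pval = cochran_q(H).pval if H.k >= 2 else float("nan")
    if H.k >= 3:
        eg = egger_intercept_test(H)
        egger_int_pval = eg.pval
    else:
        egger_int_pval = float("nan")
    if config.run_presso and H.k >= 4:
        presso_pval = presso(H, n_sim=config.presso_n_sim, seed=seed + 3).global_pval
    else:
        presso_pval = float("nan")
    if config.run_reverse:
        try:
            reverse_pval = reverse_mr(outcome, exposure, ld, config).pval
            direction = (
                "unidirectional" if reverse_pval >= config.alpha_sig else "reverse_significant"
            )
        except NoInstrumentsError:
            reverse_pval = float("nan")
            direction = "reverse_untestable"
    else:
        reverse_pval = float("nan")
        direction = ""
    pvals = [results[m].pval if results[m] is not None else float("nan") for m in METHOD_NAMES]
    tier = classify_tier(pvals, alpha_sig=config.alpha_sig)
    n_sig = sum(1 for p in pvals if not np.isnan(p) and p < config.alpha_sig)
    return ScreenRow(
        exposure_id=exposure.study_id,
        k=H.k,
        results=results,
        q_pval=q_pval,
        egger_intercept_pval=egger_int_pval,
        presso_global_pval=presso_pval,
        reverse_pval=reverse_pval,
        tier=tier,
        n_methods_significant=n_sig,
        direction=direction,
    )


def _failed_row(exposure_id: str, reason: str) -> ScreenRow:
    return ScreenRow(
        exposure_id=exposure_id,
        k=0,
        results={m: None for m in METHOD_NAMES},
        q_pval=float("nan"),
        egger_intercept_pval=float("nan"),
        presso_global_pval=float("nan"),
        reverse_pval=float("nan"),
        tier="none",
        n_methods_significant=0,
        failure_reason=reason,
    )


def screen(
    exposures: list[SummaryStudy],
    outcome: SummaryStudy,
    ld,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen many exposures against one outcome.

    Returns one row per exposure sorted by IVW p-value (failures last), with
    per-method estimates, sensitivity p-values, the evidence tier and BH-FDR
    q-values across the screen's IVW p-values. Per-exposure randomness is
    seeded from ``seed`` and the exposure id, so output is invariant to the
    input order of ``exposures``.
    """
    if not exposures:
        raise ValueError("no exposures")
    config = config or PipelineConfig()
    rows: list[ScreenRow] = []
    for exposure in exposures:
        try:
            rows.append(
                _screen_one(
                    exposure, outcome, ld, config, _exposure_seed(seed, exposure.study_id)
                )
            )
        except MedimrError as exc:
            rows.append(_failed_row(exposure.study_id, str(exc)))

    records = []
    for row in rows:
        rec = {
            "exposure_id": row.exposure_id,
            "k": row.k,
            "n_methods_significant": row.n_methods_significant,
            "tier": row.tier,
            "q_pval": row.q_pval,
            "egger_intercept_pval": row.egger_intercept_pval,
            "presso_global_pval": row.presso_global_pval,
            "reverse_pval": row.reverse_pval,
            "direction": row.direction,
            "failure_reason": row.failure_reason,
        }
        for m in METHOD_NAMES:
            res = row.results.get(m)
            prefix = m.lower()
            if res is None:
                rec.update(
                    {
                        f"{prefix}_beta": float("nan"),
                        f"{prefix}_se": float("nan"),
                        f"{prefix}_pval": float("nan"),
                        f"{prefix}_or": float("nan"),
                        f"{prefix}_or_lo95": float("nan"),
                        f"{prefix}_or_hi95": float("nan"),
                    }
                )
            else:
                rec.update(
                    {
                        f"{prefix}_beta": res.beta,
                        f"{prefix}_se": res.se,
                        f"{prefix}_pval": res.pval,
                        f"{prefix}_or": res.or_point,
                        f"{prefix}_or_lo95": res.or_low,
                        f"{prefix}_or_hi95": res.or_high,
                    }
                )
        records.append(rec)
    table = pd.DataFrame(records)

    fdr_q = np.full(len(table), np.nan)
    have_p = table["ivw_pval"].notna().to_numpy()
    if have_p.any():
        _, q, _, _ = multipletests(table.loc[have_p, "ivw_pval"], method="fdr_bh")
        fdr_q[have_p] = q
    table["fdr_q"] = fdr_q

    if config.tier_on_fdr:
        # re-tier using the FDR-adjusted IVW p-value in the primary slot
        new_tiers = []
        for i, rec in table.iterrows():
            pv = [rec["fdr_q"]] + [rec[f"{m.lower()}_pval"] for m in METHOD_NAMES[1:]]
            new_tiers.append(classify_tier(pv, alpha_sig=config.alpha_sig))
        table["tier"] = new_tiers

    table = table.sort_values(
        ["ivw_pval", "exposure_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return table


def write_screen_table(table: pd.DataFrame, path) -> None:
    """Write the screen table as a TSV with a stable column order."""
    table.to_csv(path, sep="\t", index=False)
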