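"""Instrument selection: genome-wide significance, LD clumping, strength.

Selection proceeds in three stages. Candidates must associate with the
exposure at p < 1e-5 (the relaxed threshold conventional for molecular
traits with few genome-wide-significant hits), survive greedy LD clumping
(window 10,000 kb, r² < 0.001), and have an F-statistic of at least 10,
computed from the variance explained:

    R² = 2·MAF·(1−MAF)·β²,   F = R²·(N−2)/(1−R²).

Every exclusion is recorded in an audit trail so that
|input| = |retained| + |excluded| at each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LdMatrixError
from .gwas_data import SummaryStudy

DEFAULT_PVAL_THRESHOLD = 1e-5
DEFAULT_WINDOW_KB = 10_000.0
DEFAULT_R2_MAX = 0.001
DEFAULT_F_MIN = 10.0


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure plus the full exclusion audit.

    ``table`` has one row per retained SNP (snp_id, pval, r2_explained,
    f_stat); ``exclusions`` lists (snp_id, stage, detail) with stage in
    {pval, clump, weak, exposure_assoc}.
    """

    exposure_id: str
    snp_ids: list[str]
    table: pd.DataFrame
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snp_ids)


def select_by_pvalue(study: SummaryStudy, threshold: float = DEFAULT_PVAL_THRESHOLD) -> list[str]:
    """SNP ids with pval strictly below ``threshold``.

    Ordered by ascending pval, ties broken lexicographically by snp_id.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    d = study.df
    hits = d.loc[d["pval"] < threshold, ["snp_id", "pval"]]
    hits = hits.sort_values(["pval", "snp_id"], kind="mergesort")
    return hits["snp_id"].tolist()


def ld_clump(
    candidates,
    study: SummaryStudy,
    ld: pd.DataFrame,
    window_kb: float = DEFAULT_WINDOW_KB,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly promote the remaining candidate with the smallest pval to
    index SNP and remove every remaining candidate on the same chromosome
    within ±``window_kb`` whose squared correlation with it is >= ``r2_max``.
    Output order is index-selection order; the result depends only on pvals,
    positions and LD, not on the input ordering of ``candidates``.
    """
    candidates = list(candidates)
    missing = [s for s in candidates if s not in ld.index or s not in ld.columns]
    if missing:
        raise LdMatrixError(f"candidate SNP(s) missing from LD matrix: {missing[:5]}")

    sub = study.subset(candidates)
    pval = dict(zip(sub["snp_id"], sub["pval"]))
    chrom = dict(zip(sub["snp_id"], sub["chrom"].astype(str)))
    pos = dict(zip(sub["snp_id"], sub["pos"].astype(np.int64)))

    order = sorted(candidates, key=lambda s: (pval[s], s))
    window_bp = window_kb * 1000.0
    remaining = set(candidates)
    kept: list[str] = []
    for idx in order:
        if idx not in remaining:
            continue
        kept.append(idx)
        remaining.discard(idx)
        row = ld.loc[idx]
        for other in [s for s in remaining]:
            if chrom[other] != chrom[idx]:
                continue
            if abs(pos[other] - pos[idx]) > window_bp:
                continue
            if float(row[other]) ** 2 >= r2_max:
                remaining.discard(other)
    return kept


def r2_from_maf(eaf: float, beta: float) -> float:
    """Variance in the exposure explained by a SNP: 2·MAF·(1−MAF)·β²."""
    if not 0.0 <= eaf <= 1.0:
        raise ValueError("eaf must lie in [0, 1]")
    maf = min(eaf, 1.0 - eaf)
    return 2.0 * (1.0 - maf) * maf * beta * beta


def f_statistic(r2: float, n: float) -> float:
    """Instrument-strength F-statistic: R²·(N−2)/(1−R²)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return r2 * (n - 2.0) / (1.0 - r2)


def filter_weak(
    snp_ids,
    study: SummaryStudy,
    f_min: float = DEFAULT_F_MIN,
    prior_exclusions: list[tuple[str, str, str]] | None = None,
) -> InstrumentSet:
    """Drop instruments with F below ``f_min`` (strict: F >= f_min is kept).

    Per-SNP sample size is used when present, the study-level default
    otherwise; SNPs with no usable eaf or n are excluded with an audit
    detail and a warning.
    """
    exclusions = list(prior_exclusions) if prior_exclusions else []
    rows = []
    kept: list[str] = []
    for snp in snp_ids:
        rec = study.get(snp)
        n = rec.n
        if np.isnan(n):
            n = study.default_n if study.default_n is not None else np.nan
        if np.isnan(rec.eaf):
            exclusions.append((snp, "weak", "no_eaf"))
            warnings.warn(f"{snp}: no eaf available, excluded from instruments", stacklevel=2)
            continue
        if np.isnan(n):
            exclusions.append((snp, "weak", "no_n"))
            warnings.warn(f"{snp}: no sample size available, excluded", stacklevel=2)
            continue
        r2 = r2_from_maf(rec.eaf, rec.beta)
        if r2 >= 1.0:
            exclusions.append((snp, "weak", "r2_out_of_range"))
            continue
        f = f_statistic(r2, n)
        if f >= f_min:
            kept.append(snp)
            rows.append((snp, rec.pval, r2, f))
        else:
            exclusions.append((snp, "weak", f"f_stat={f:.4g}"))
    table = pd.DataFrame(rows, columns=["snp_id", "pval", "r2_explained", "f_stat"])
    return InstrumentSet(
        exposure_id=study.study_id, snp_ids=kept, table=table, exclusions=exclusions
    )


def select_instruments(
    study: SummaryStudy,
    ld: pd.DataFrame,
    pval_threshold: float = DEFAULT_PVAL_THRESHOLD,
    window_kb: float = DEFAULT_WINDOW_KB,
    r2_max: float = DEFAULT_R2_MAX,
    f_min: float = DEFAULT_F_MIN,
) -> InstrumentSet:
    """Full selection pipeline: p-value screen -> LD clump -> weak-instrument filter."""
    candidates = select_by_pvalue(study, pval_threshold)
    candidate_set = set(candidates)
    exclusions = [
        (s, "pval", f">= {pval_threshold:g}") for s in study.snp_ids if s not in candidate_set
    ]
    clumped = ld_clump(candidates, study, ld, window_kb=window_kb, r2_max=r2_max)
    clumped_set = set(clumped)
    exclusions += [(s, "clump", "in LD with stronger index SNP") for s in candidates if s not in clumped_set]
    return filter_weak(clumped, study, f_min=f_min, prior_exclusions=exclusions)
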