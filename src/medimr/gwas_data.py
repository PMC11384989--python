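"""Data model and I/O for GWAS summary statistics, plus allele harmonization.

A study is a table of per-SNP associations (effect allele, beta, SE, ...).
Two-sample MR needs the exposure and outcome effects expressed for the same
effect allele at every instrument; :func:`harmonize` performs that alignment,
dropping strand-ambiguous palindromic variants whose allele frequency is too
close to 0.5 to resolve orientation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import two_sided_normal_p
from .errors import ConfigurationError, NoInstrumentsError

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: canonical internal field order
STANDARD_FIELDS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: default column names follow the GWAS-SSF convention
DEFAULT_COLUMN_MAP = {
    "snp_id": "rsid",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")


@dataclass
class SnpAssociation:
    """One SNP's summary statistics in one study.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits); ``eaf`` its frequency; ``pval_derived``
    marks p-values reconstructed from beta/se rather than read from file.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    pval_derived: bool = False

    def validate(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be single A/C/G/T characters")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not np.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf must lie in [0, 1]")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval must lie in (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS


@dataclass
class SummaryStudy:
    """An ordered collection of :class:`SnpAssociation` rows for one trait.

    Backed by a :class:`pandas.DataFrame` with the :data:`STANDARD_FIELDS`
    columns plus ``pval_derived``; ``snp_id`` is unique.
    """

    study_id: str
    trait_name: str
    df: pd.DataFrame
    trait_type: str = "quantitative"
    default_n: float | None = None
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in STANDARD_FIELDS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"study table missing columns: {missing}")
        if "pval_derived" not in self.df.columns:
            self.df = self.df.assign(pval_derived=False)
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ConfigurationError(f"duplicate snp_id in study {self.study_id}: {dups[:5]}")
        self._index = {s: i for i, s in enumerate(self.df["snp_id"])}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def get(self, snp_id: str) -> SnpAssociation:
        row = self.df.iloc[self._index[snp_id]]
        return SnpAssociation(
            snp_id=row["snp_id"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=float(row["n"]),
            pval_derived=bool(row["pval_derived"]),
        )

    def records(self):
        """Iterate over rows as :class:`SnpAssociation` objects."""
        for snp_id in self.df["snp_id"]:
            yield self.get(snp_id)

    def subset(self, snp_ids) -> pd.DataFrame:
        idx = [self._index[s] for s in snp_ids]
        return self.df.iloc[idx]


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``df`` has one row per retained SNP with columns snp_id, beta_exp, se_exp,
    beta_out, se_out, eaf_exp. ``dropped`` lists (snp_id, reason) for every
    requested SNP that could not be harmonized.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    HARMONIZED_COLUMNS = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp"]

    @property
    def k(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def arrays(self):
        d = self.df
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_study(
    path,
    column_map: dict | None = None,
    study_id: str | None = None,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
    delimiter: str | None = None,
) -> SummaryStudy:
    """Read a delimited summary-statistics table into a :class:`SummaryStudy`.

    ``column_map`` maps standard field names (:data:`STANDARD_FIELDS`) to the
    file's column names; unspecified fields fall back to GWAS-SSF names.
    Rows with missing or non-numeric beta/se are skipped and reported in
    ``study.skipped``. If the p-value column is absent, p-values are derived
    from 2·(1−Φ(|beta/se|)) and flagged ``pval_derived``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in raw.columns:
            raise ConfigurationError(
                f"mandatory column '{cmap[fld]}' (field '{fld}') not found in {path}"
            )

    present = {fld: col for fld, col in cmap.items() if col in raw.columns}
    out = pd.DataFrame(index=raw.index)
    out["snp_id"] = raw[present["snp_id"]].str.strip()
    out["chrom"] = raw[present["chrom"]].str.strip() if "chrom" in present else "0"
    out["effect_allele"] = raw[present["effect_allele"]].str.strip().str.upper()
    out["other_allele"] = raw[present["other_allele"]].str.strip().str.upper()

    def numeric(fld, default=np.nan):
        if fld not in present:
            return pd.Series(default, index=raw.index, dtype=float), pd.Series(
                "", index=raw.index
            )
        s = raw[present[fld]].str.strip()
        coerced = pd.to_numeric(s, errors="coerce")
        # re-parse valid entries through numpy's correctly-rounded strtod so
        # written values round-trip to full precision
        valid = coerced.notna().to_numpy()
        precise = np.full(len(s), np.nan)
        precise[valid] = np.asarray(s[valid], dtype=np.float64)
        coerced = pd.Series(precise, index=s.index)
        blank = s == ""
        reason = pd.Series("", index=raw.index)
        reason[blank] = f"missing {fld}"
        reason[~blank & coerced.isna()] = f"non-numeric {fld}"
        return coerced, reason

    pos, _ = numeric("pos", default=0.0)
    eaf, _ = numeric("eaf")
    beta, beta_reason = numeric("beta")
    se, se_reason = numeric("se")
    pval, _ = numeric("pval")
    n, _ = numeric("n")

    skip_reason = beta_reason.where(beta_reason != "", se_reason)
    bad_se = se.notna() & (se <= 0)
    skip_reason[bad_se & (skip_reason == "")] = "nonpositive se"
    bad_alleles = (
        ~out["effect_allele"].isin(list(VALID_ALLELES))
        | ~out["other_allele"].isin(list(VALID_ALLELES))
        | (out["effect_allele"] == out["other_allele"])
    )
    skip_reason[bad_alleles & (skip_reason == "")] = "invalid alleles"

    keep = skip_reason == ""
    skipped = [
        (out.loc[i, "snp_id"] or f"row{i}", skip_reason[i]) for i in raw.index[~keep]
    ]

    out = out[keep].copy()
    out["pos"] = pos[keep].fillna(0).astype(np.int64)
    out["eaf"] = eaf[keep]
    out["beta"] = beta[keep]
    out["se"] = se[keep]
    out["n"] = n[keep]
    z = out["beta"] / out["se"]
    derived_p = two_sided_normal_p(z.to_numpy())
    if "pval" in present:
        out["pval"] = pval[keep]
        need = out["pval"].isna()
        out.loc[need, "pval"] = derived_p[need.to_numpy()]
        out["pval_derived"] = need.to_numpy()
    else:
        out["pval"] = derived_p
        out["pval_derived"] = True
    out = out[STANDARD_FIELDS + ["pval_derived"]].reset_index(drop=True)

    from pathlib import Path

    sid = study_id if study_id is not None else Path(path).stem
    return SummaryStudy(
        study_id=sid,
        trait_name=trait_name if trait_name is not None else sid,
        df=out,
        trait_type=trait_type,
        skipped=skipped,
    )


def write_summary_study(study: SummaryStudy, path) -> None:
    """Write a study as a GWAS-SSF-style TSV (fixed column order).

    If the study carries skipped rows, a sidecar ``<path>.skipped.tsv``
    (snp_id, reason) is written next to it.
    """
    out = study.df.rename(columns=DEFAULT_COLUMN_MAP)
    cols = [DEFAULT_COLUMN_MAP[f] for f in STANDARD_FIELDS] + ["pval_derived"]
    buf = io.StringIO()
    out[cols].to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    if study.skipped:
        rep = pd.DataFrame(study.skipped, columns=["snp_id", "reason"])
        rep.to_csv(f"{path}.skipped.tsv", sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def harmonize(
    exposure: SummaryStudy,
    outcome: SummaryStudy,
    snp_ids,
    palindromic_maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Orientation rules per SNP:

    * same allele pair, same order: outcome beta copied;
    * swapped (effect <-> other): outcome beta negated;
    * palindromic (A/T or C/G) variants: dropped as ambiguous when the
      exposure minor-allele frequency is >= ``palindromic_maf_threshold``
      (or unknown); otherwise oriented by allele-frequency concordance;
    * any other allele pair: dropped as ``allele_mismatch``.

    No strand (complement) correction is attempted for non-palindromic
    mismatches; they are reported as mismatches.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise NoInstrumentsError("no instruments")

    missing_exp = [s for s in snp_ids if s not in exposure]
    if missing_exp:
        raise ValueError(f"snp(s) absent from exposure study: {missing_exp[:5]}")

    rows = []
    dropped: list[tuple[str, str]] = []
    for snp in snp_ids:
        e = exposure.get(snp)
        if snp not in outcome:
            dropped.append((snp, "absent_in_outcome"))
            continue
        o = outcome.get(snp)

        if _is_palindromic(e.effect_allele, e.other_allele):
            maf = min(e.eaf, 1.0 - e.eaf) if not np.isnan(e.eaf) else np.nan
            if np.isnan(maf) or maf >= palindromic_maf_threshold:
                dropped.append((snp, "palindromic_ambiguous"))
                continue
            if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
                dropped.append((snp, "allele_mismatch"))
                continue
            # orient by frequency: the minor allele must be minor in both studies
            if not np.isnan(o.eaf):
                same = (e.eaf < 0.5) == (o.eaf < 0.5)
            else:
                same = o.effect_allele == e.effect_allele
            beta_out = o.beta if same else -o.beta
        elif (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            beta_out = o.beta
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            beta_out = -o.beta
        else:
            dropped.append((snp, "allele_mismatch"))
            continue

        rows.append((snp, e.beta, e.se, beta_out, o.se, e.eaf))

    df = pd.DataFrame(rows, columns=HarmonizedSet.HARMONIZED_COLUMNS)
    if not rows:
        warnings.warn(
            f"harmonization of {exposure.study_id} vs {outcome.study_id} retained 0 SNPs",
            stacklevel=2,
        )
    return HarmonizedSet(
        exposure_id=exposure.study_id,
        outcome_id=outcome.study_id,
        df=df,
        dropped=dropped,
    )


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square LD correlation matrix (TSV, SNP ids as index and header)."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")
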