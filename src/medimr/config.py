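"""Shared pipeline configuration: every threshold in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class PipelineConfig:
    """Thresholds and options shared by the screening and mediation pipelines.

    Defaults encode the conventional choices: instrument p < 1e-5, clumping
    window 10,000 kb at r² < 0.001, F >= 10, 0.05 significance throughout,
    multiplicative random-effects IVW.
    """

    pval_threshold: float = 1e-5
    window_kb: float = 10_000.0
    r2_max: float = 0.001
    f_min: float = 10.0
    palindromic_maf: float = 0.42
    ivw_model: str = "random_multiplicative"
    alpha_sig: float = 0.05
    n_boot: int = 1000
    mediator_exclusion_pval: float = 1e-5
    presso_n_sim: int = 1000
    run_presso: bool = True
    run_reverse: bool = False
    reverse_pval_threshold: float = 1e-5
    tier_on_fdr: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
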