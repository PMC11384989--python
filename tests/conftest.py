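import numpy as np
import pandas as pd
import pytest

from medimr.gwas_data import STANDARD_FIELDS, SummaryStudy
from medimr.synthetic import SimulationConfig, simulate_mr_study


def make_study(rows, study_id="study", **kwargs):
    """Build a SummaryStudy from a list of per-SNP dicts; sensible defaults."""
    defaults = {
        "chrom": "1",
        "pos": 0,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.0,
        "se": 0.01,
        "pval": 0.5,
        "n": 10_000,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("snp_id", f"rs{i + 1}")
        rec.update(row)
        if "pos" not in row:
            rec["pos"] = (i + 1) * 100_000
        records.append(rec)
    df = pd.DataFrame(records)[STANDARD_FIELDS]
    return SummaryStudy(study_id=study_id, trait_name=study_id, df=df, **kwargs)


def identity_ld(snp_ids):
    return pd.DataFrame(np.eye(len(snp_ids)), index=snp_ids, columns=snp_ids)


@pytest.fixture
def three_snp_harmonized():
    """The worked IVW example: three SNPs with known pooled estimate 165/725."""
    return pd.DataFrame(
        {
            "snp_id": ["a", "b", "c"],
            "beta_exp": [0.1, 0.2, 0.15],
            "se_exp": [0.01, 0.01, 0.01],
            "beta_out": [0.02, 0.05, 0.03],
            "se_out": [0.01, 0.01, 0.01],
            "eaf_exp": [0.3, 0.3, 0.3],
        }
    )


@pytest.fixture
def sim_factory():
    def make(seed=0, **overrides):
        return simulate_mr_study(SimulationConfig(seed=seed, **overrides))

    return make


def harmonized_truth(sim, target="outcome"):
    """Harmonize the true instruments against one of the simulated studies."""
    from medimr.gwas_data import harmonize

    tgt = {"outcome": sim.outcome, "mediator": sim.mediator}[target]
    return harmonize(sim.exposure, tgt, sim.truth.instrument_ids)
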