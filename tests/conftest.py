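import numpy as np
import pandas as pd
import pytest

from cytomr.sumstats import RECORD_COLUMNS, SummaryStats


def make_records(
    variant_ids,
    pos=None,
    chrom="1",
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.05,
    p=None,
    n=1000,
):
    """Build a valid records frame, broadcasting scalars."""
    k = len(variant_ids)

    def col(v):
        return np.broadcast_to(np.asarray(v), (k,)).copy()

    beta = col(beta).astype(float)
    se = col(se).astype(float)
    if p is None:
        from scipy import stats
        p = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    df = pd.DataFrame({
        "variant_id": list(variant_ids),
        "chrom": col(chrom),
        "pos": col(pos if pos is not None else np.arange(1, k + 1) * 1000),
        "effect_allele": col(ea),
        "other_allele": col(oa),
        "eaf": col(eaf).astype(float),
        "beta": beta,
        "se": se,
        "p": col(p).astype(float),
        "n": col(n),
    })
    return df[RECORD_COLUMNS]


def make_sumstats(trait_id="trait", trait_type="quantitative", **kwargs):
    return SummaryStats(trait_id=trait_id, trait_type=trait_type,
                        records=make_records(**kwargs))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
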