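import numpy as np
import pandas as pd
import pytest

from mrmed.summary_data import HarmonisedSet, LDInfo, SummaryStats


def make_stats(
    trait_id: str,
    betas,
    ses,
    pvals=None,
    eafs=None,
    n=100_000,
    ids=None,
    ea="A",
    oa="G",
    trait_type="quantitative",
) -> SummaryStats:
    """Build a SummaryStats from plain vectors (helper, not a fixture)."""
    from scipy.stats import norm

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    j = len(betas)
    if pvals is None:
        pvals = np.clip(2 * norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    if eafs is None:
        eafs = np.full(j, 0.3)
    if ids is None:
        ids = [f"rs{i + 1}" for i in range(j)]
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": np.arange(1, j + 1) * 1000,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eafs,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n": n,
        }
    )
    return SummaryStats(trait_id=trait_id, variants=df, trait_type=trait_type)


def make_harmonised(bx, sx, by, sy, traits=("X", "Y")) -> HarmonisedSet:
    bx = np.asarray(bx, float)
    sx = np.asarray(sx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    j = len(bx)
    return HarmonisedSet(
        traits=list(traits),
        variant_ids=[f"rs{i + 1}" for i in range(j)],
        beta=np.column_stack([bx, by]),
        se=np.column_stack([sx, sy]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)


@pytest.fixture
def empty_ld():
    return LDInfo()


@pytest.fixture
def toy_harmonised(rng):
    """10 variants generated on bY = 0.4*bX with noise."""
    bx = rng.uniform(0.05, 0.2, 10) * rng.choice([-1, 1], 10)
    sx = np.full(10, 0.005)
    sy = np.full(10, 0.01)
    by = 0.4 * bx + rng.normal(0, sy)
    return make_harmonised(bx, sx, by, sy)
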