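import numpy as np
import pandas as pd
import pytest

from carriermr.scores import GeneticScoreModel
from carriermr.sumstats import HarmonizedInstrumentSet


def make_assoc(variant_ids, ea, oa, eaf, beta, se, chrom=None, pos=None):
    n = len(variant_ids)
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chr": chrom if chrom is not None else [1] * n,
            "pos": pos if pos is not None else list(range(100, 100 + n)),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
        }
    )


def make_iset(bx, sx, by, sy, mediators=None):
    """Build a HarmonizedInstrumentSet directly from aligned arrays."""
    bx = np.asarray(bx, float)
    n = bx.size
    data = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(n)],
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "eaf": [0.3] * n,
            "beta_exposure": bx,
            "se_exposure": np.asarray(sx, float),
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sy, float),
        }
    )
    labels = []
    for label, (bm, sm) in (mediators or {}).items():
        data[f"beta_{label}"] = np.asarray(bm, float)
        data[f"se_{label}"] = np.asarray(sm, float)
        labels.append(label)
    return HarmonizedInstrumentSet(data=data, mediators=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def score_model():
    r = np.random.default_rng(7)
    n = 40
    return GeneticScoreModel(
        variant_id=tuple(f"rs{i + 1}" for i in range(n)),
        effect_allele=tuple(r.choice(list("ACGT"), n)),
        weight=tuple(r.normal(0, 0.08, n)),
        eaf=tuple(r.uniform(0.05, 0.95, n)),
        label="ANM-GS",
    )


def random_iset(rng, n=30, theta=0.05):
    """Random homogeneous instrument set (no pleiotropy)."""
    bx = rng.normal(0, 0.08, n)
    sx = rng.uniform(0.004, 0.012, n)
    sy = rng.uniform(0.01, 0.04, n)
    by = theta * bx + sy * rng.standard_normal(n)
    return make_iset(bx + sx * rng.standard_normal(n), sx, by, sy)
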