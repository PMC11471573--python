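import numpy as np
import pandas as pd
import pytest

from mrscreen.harmonize import ALIGNED, HarmonizedPair
from mrscreen.sumstats import CANONICAL_COLUMNS, GwasSumStats


def make_sumstats(trait_id="trait", **columns) -> GwasSumStats:
    """Small canonical-frame builder; unspecified optional columns become NA."""
    n = len(columns["snp"])
    defaults = {
        "chr": ["1"] * n,
        "pos": list(range(1_000, 1_000 + n)),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [np.nan] * n,
        "beta": [0.1] * n,
        "se": [0.02] * n,
        "pval": [1e-9] * n,
        "n": [np.nan] * n,
    }
    defaults.update(columns)
    df = pd.DataFrame({c: defaults[c] for c in CANONICAL_COLUMNS})
    df["n"] = pd.array(df["n"], dtype="Int64") if df["n"].notna().any() else df["n"]
    return GwasSumStats(trait_id, df)


def make_pairs(beta_x, beta_y, se_y, se_x=None, snp_prefix="rs") -> list[HarmonizedPair]:
    """Aligned harmonized pairs from plain arrays."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), beta_x.shape)
    se_x = (np.full_like(beta_x, 1e-6) if se_x is None
            else np.broadcast_to(np.asarray(se_x, dtype=float), beta_x.shape))
    return [
        HarmonizedPair(f"{snp_prefix}{i + 1}", bx, sx, by, sy, ALIGNED)
        for i, (bx, sx, by, sy) in enumerate(zip(beta_x, se_x, beta_y, se_y))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tmp_tsv(tmp_path):
    def _write(text, name="stats.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p
    return _write
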