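import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_reference.py

from gamescan.sim import PopulationSpec, SimConfig
from gamescan.types import GenotypeCalls


def make_calls(dosage, dp=None, ad=None, gq=None):
    """Hand-built GenotypeCalls with benign read evidence where unspecified."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if dp is None:
        dp = np.full((n, m), 30, dtype=np.int32)
    else:
        dp = np.asarray(dp, dtype=np.int32)
    if ad is None:
        alt = np.where(dosage == 1, dp // 2, np.where(dosage == 2, dp, 0))
        alt = np.where(dosage == -1, 0, alt)
        ad = np.stack([np.where(dosage == -1, 0, dp) - alt, alt], axis=2).astype(np.int32)
    else:
        ad = np.asarray(ad, dtype=np.int32)
    if gq is None:
        gq = np.full((n, m), 99, dtype=np.int16)
    else:
        gq = np.asarray(gq, dtype=np.int16)
    return GenotypeCalls(dosage=dosage, dp=dp, ad=ad, gq=gq)


def make_variants(n, chrom="chrS", spacing=1000, **overrides):
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "ref": "A",
            "alt": "T",
            "mq": 60.0,
            "mq0f": 0.0,
            "indel_distance": np.inf,
            "is_indel": False,
            "is_multiallelic": False,
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def null_cohort():
    """Panmictic 48 gamecock + 62 nongame cohort, no selected locus."""
    import gamescan

    cfg = SimConfig(
        n_variants=800,
        chrom_length_bp=800_000,
        populations=(
            PopulationSpec("pop", "gamecock", 48, 0.0),
            PopulationSpec("pop", "nongame", 62, 0.0),
        ),
        selected_locus=None,
        missing_rate=0.02,
        seed=1234,
    )
    samples, variants, calls = gamescan.simulate_cohort(cfg)
    return cfg, samples, variants, calls


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-shaped cohort with a selected locus and linked block."""
    import gamescan

    cfg = gamescan.default_config(seed=42)
    samples, variants, calls = gamescan.simulate_cohort(cfg)
    return cfg, samples, variants, calls
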