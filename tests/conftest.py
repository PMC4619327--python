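import numpy as np
import pytest
from hypothesis import settings

from wntlineage.lineage_model import CellName, CellRecord, LineageTree
from wntlineage.synthetic_data import SynthParams, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def tiny_tree() -> LineageTree:
    """Handmade three-generation tree under ABa with known blots.

    ABa(10) -> ABaa(4), ABap(8); ABap -> ABapa(2), ABapp(6).
    """
    recs = [
        CellRecord("ABa", birth_time=0.0, end_time=10.0, blot=10.0),
        CellRecord("ABaa", birth_time=10.0, end_time=30.0, blot=4.0),
        CellRecord("ABap", birth_time=10.0, end_time=20.0, blot=8.0),
        CellRecord("ABapa", birth_time=20.0, end_time=30.0, blot=2.0),
        CellRecord("ABapp", birth_time=20.0, end_time=30.0, blot=6.0),
    ]
    return LineageTree(recs, embryo_id="tiny", reporter="Venus::SYS-1")


@pytest.fixture(scope="session")
def wt_group():
    """Wild-type-like SYS-1 study condition: 8 embryos at the 350-cell
    stage, posterior boost = 3 noise SDs, planted 74% cousin enrichment."""
    trees, truth, _ = simulate_dataset(SynthParams(), n_embryos=8, seed=20231)
    return trees, truth


@pytest.fixture(scope="session")
def clean_group():
    """Noise-free, a-p-only variant for exact closed-form checks."""
    params = SynthParams(sigma=0.0, lr_dv_fraction=0.0, embryo_scale_sd=0.0,
                         cycle_jitter=0.05)
    trees, truth, _ = simulate_dataset(params, n_embryos=3, seed=7)
    return trees, truth, params


def quartet_tree() -> LineageTree:
    """Single grandparent quartet: ABpl -> (ABpla, ABplp) -> 4 grandchildren.

    HH cell ABplpp has blot 6, its LH cousin ABplap has blot 4.
    """
    vals = {
        "ABpl": 1.0, "ABpla": 2.0, "ABplp": 5.0,
        "ABplaa": 1.0, "ABplap": 4.0, "ABplpa": 2.0, "ABplpp": 6.0,
    }
    recs = [
        CellRecord(n, birth_time=float(i), end_time=float(i) + 10.0, blot=v)
        for i, (n, v) in enumerate(vals.items())
    ]
    return LineageTree(recs, embryo_id="quartet", reporter="Venus::SYS-1")


@pytest.fixture
def one_quartet() -> LineageTree:
    return quartet_tree()
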