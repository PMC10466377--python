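import warnings

import pandas as pd
import pytest

from delblocks import curation, synthdel

warnings.filterwarnings("ignore", category=FutureWarning)


def make_records(rows):
    """Small labeled record table from (bb1, bb2, bb3, binder) tuples."""
    df = pd.DataFrame(rows, columns=["bb1", "bb2", "bb3", "binder"])
    df["read_count"] = df["binder"] * 100
    df["compound_smiles"] = [f"{a}.{b}.{c}" for a, b, c in zip(df.bb1, df.bb2, df.bb3)]
    return df


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic library (20 x 20 x 50, full factorial)."""
    return synthdel.generate(synthdel.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_labeled(default_dataset):
    """Default library labeled against its true Poisson background rate."""
    return curation.label_binders(
        default_dataset.records, lambda0=default_dataset.config.lambda_background
    )


@pytest.fixture(scope="session")
def small_labeled():
    """A ~1000-record random subsample library for brute-force comparisons."""
    cfg = synthdel.SyntheticConfig(n_bb=(8, 8, 10), library_size=1000, seed=3)
    ds = synthdel.generate(cfg)
    return curation.label_binders(ds.records, lambda0=cfg.lambda_background)
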