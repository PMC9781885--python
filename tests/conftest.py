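import logging

import pandas as pd
import pytest

from matchload.features import apply_ceiling, build_minute_table
from matchload.simulate import SimConfig, simulate_corpus

logging.getLogger("matchload").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_games=3, players_per_game=4, seed=123)


@pytest.fixture(scope="session")
def small_corpus(small_cfg):
    return simulate_corpus(small_cfg)


@pytest.fixture(scope="session")
def small_table(small_corpus):
    tabs = [build_minute_table(g.events, g.windows, g.meta) for g in small_corpus]
    return apply_ceiling(pd.concat(tabs, ignore_index=True))


@pytest.fixture(scope="session")
def small_truth(small_corpus):
    return pd.concat([g.truth for g in small_corpus], ignore_index=True)
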