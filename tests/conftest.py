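import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cleavesite as cs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def background():
    return cs.load_background()


@pytest.fixture(scope="session")
def small_corpus():
    """A small simulated corpus with default (study-condition) parameters."""
    return cs.simulate_corpus(cs.SimConfig(n_sequences=20, seed=7))


@pytest.fixture(scope="session")
def candidate_set(small_corpus):
    return cs.candidate_windows(small_corpus)


def make_window(residues, site_index=None, label=None, parent_length=None,
                cfg=cs.WindowConfig(), **kw):
    """Build a Window directly from a padded window string."""
    assert len(residues) == cfg.length
    return cs.Window(
        parent_id="w",
        site_index=site_index if site_index is not None else cfg.w_pre + 1,
        parent_length=parent_length if parent_length is not None else cfg.length,
        residues=residues,
        label=label,
        **kw,
    )
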