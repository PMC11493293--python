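"""Shared fixtures.

The expensive fixture is ``e2e_result``: one full end-to-end run at the
package's default desk scale (20 clips per class, 12-frame 64×64 clips,
reduced backbone, 20 epochs, seed 7), shared session-wide by the tests
that assert on trained-model behavior.
"""

from __future__ import annotations

import numpy as np
import pytest

from feedstream.config import load_config
from feedstream.pipeline import end_to_end


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def e2e_result(tmp_path_factory):
    """Default-configuration end-to-end run (trained models + report)."""
    out_dir = tmp_path_factory.mktemp("e2e_run")
    config = load_config(None)
    return end_to_end(config, out_dir=out_dir)
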