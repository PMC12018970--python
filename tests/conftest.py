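import numpy as np
import pytest

from poultrans import fixtures as fx


@pytest.fixture(scope="session")
def golden_dir(tmp_path_factory):
    """The fixed 20-image seed-7 corpus, generated once per session."""
    out = tmp_path_factory.mktemp("golden")
    spec = fx.golden_spec()
    records, json_path = fx.generate_corpus(spec, out)
    return {"dir": out, "spec": spec, "records": records, "json": json_path}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
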