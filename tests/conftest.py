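"""Shared fixtures: expensive key sets and backends are session-scoped."""

import numpy as np
import pytest

from fhelogit import EncryptionParams, fv
from fhelogit.batching import SlotCodec
from fhelogit.bootstrap import FVBackend, TraceBackend
from fhelogit.params import preset


@pytest.fixture(scope="session")
def small_params():
    """Cheap FV instantiation for scheme-level tests (no bootstrapping)."""
    return EncryptionParams(n=16, q=1 << 120, p=5, r=2, fp_l=0, fp_f=1)


@pytest.fixture(scope="session")
def small_keys(small_params):
    return fv.keygen(small_params, seed=11)


@pytest.fixture(scope="session")
def small_codec(small_params):
    return SlotCodec(small_params.n, small_params.p, small_params.r)


@pytest.fixture(scope="session")
def be_p5():
    """Real backend, n=2, p=5, r=2, e=4: exhaustive-sweep scale."""
    return FVBackend(preset("toy-p5"), seed=21)


@pytest.fixture(scope="session")
def be_p3():
    """Real backend, n=2, p=3, r=2, e=5 (k=1, Galois-ring slot)."""
    return FVBackend(preset("toy-p3"), seed=22)


@pytest.fixture(scope="session")
def be_train():
    """Real backend, n=8, p=17, r=3, e=6, k=8: encrypted-training scale."""
    return FVBackend(preset("toy-train"), seed=23)


@pytest.fixture()
def trace_train():
    params = preset("toy-train")
    return TraceBackend(params.p, params.r, params.boot_e,
                        SlotCodec(params.n, params.p, params.r).k)


@pytest.fixture()
def trace127():
    """Trace emulator at the production base p=127 (r=3, k=8)."""
    return TraceBackend(127, 3, 5, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
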