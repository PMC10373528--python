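import numpy as np
import pytest

from stripetime.boundary import classify_boundary
from stripetime.config import NoiseParams, SimConfig
from stripetime.datatypes import EmbryoDataset, NucleusTrace
from stripetime.synthetic import simulate_dataset, simulate_embryo
from stripetime.traces import preprocess_embryo


@pytest.fixture(scope="session")
def endogenous_pairs():
    """Five default endogenous embryos through preprocess + classify."""
    cfg = SimConfig(rng_seed=11)
    out = []
    for embryo, truth in simulate_dataset(cfg, 5, base_seed=11):
        processed = preprocess_embryo(embryo, background=cfg.background)
        out.append((processed, classify_boundary(processed), truth))
    return out


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = SimConfig(rng_seed=3, noise=NoiseParams.zero())
    return simulate_embryo(cfg), cfg


@pytest.fixture(scope="session")
def noiseless_processed(noiseless_sim):
    (embryo, truth), cfg = noiseless_sim
    processed = preprocess_embryo(embryo, background=cfg.background)
    return processed, classify_boundary(processed), truth


def make_embryo(traces_y=None, protein=None, spot=None, t=None, frame_interval=20.0,
                neighbors=None, manual_gastrulation=0.0):
    """Small hand-built embryo for unit tests."""
    if t is None:
        t = -20.0 + np.arange(91) / 3.0
    keys = set()
    for d in (traces_y, protein, spot):
        if d:
            keys |= set(d)
    traces = {}
    for k in sorted(keys):
        y = np.asarray(traces_y[k], float) if traces_y and k in traces_y else np.zeros_like(t)
        p = np.asarray(protein[k], float) if protein and k in protein else np.ones_like(t)
        s = np.asarray(spot[k], float) if spot and k in spot else np.zeros_like(t)
        traces[k] = NucleusTrace(k, np.full_like(t, float(k)), y, p, s)
    return EmbryoDataset(
        embryo_id="toy",
        construct="endogenous",
        frame_interval=frame_interval,
        t=t,
        traces=traces,
        neighbors=neighbors or {k: set() for k in keys},
        manual_gastrulation=manual_gastrulation,
    )
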