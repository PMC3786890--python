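import numpy as np
import pytest
from hypothesis import settings

import kinesim as ks

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_params() -> ks.MotorParams:
    """Measured kinesin-1 kinetics (v, D, k_on, k_off) in CAD neurites."""
    return ks.PAPER_PARAMS


@pytest.fixture(scope="session")
def geom30() -> ks.Geometry1D:
    return ks.Geometry1D(30.0)


@pytest.fixture(scope="session")
def lbb_pde_steady(paper_params, geom30):
    """PDE steady state of the Loose Bucket Brigade, reused across tests."""
    return ks.steady_state_numeric(
        ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, ks.SolverConfig(dx=0.01), J=1.0
    )


def expected_counts_from_field(field, edges, n_total) -> np.ndarray:
    """Bin-integrated expected motor counts from a PDE density field."""
    cum = np.concatenate([[0.0], np.cumsum(field.c_tot) * field.dx])
    xg = np.concatenate([[0.0], field.x + field.dx / 2])
    cdf = np.interp(edges, xg, cum)
    return np.diff(cdf) / cum[-1] * n_total


def merge_low_bins(obs, exp, min_expected=5.0):
    """Pool adjacent bins until every expected count reaches min_expected."""
    o_out, e_out = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, exp):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            o_out.append(o_acc)
            e_out.append(e_acc)
            o_acc = e_acc = 0.0
    o_out[-1] += o_acc
    e_out[-1] += e_acc
    obs, exp = np.asarray(o_out, float), np.asarray(e_out, float)
    exp *= obs.sum() / exp.sum()
    return obs, exp
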