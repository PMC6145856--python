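import numpy as np
import pandas as pd
import pytest

from docprog.preprocess import BoldRun
from docprog.roi import Roi, RoiSet
from docprog.synthetic import CohortSpec, gen_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (63 patients, 30 controls, 22 ROIs)."""
    spec = CohortSpec(seed=7)
    subjects, table, truth = gen_cohort(spec)
    return spec, subjects, table, truth


@pytest.fixture(scope="session")
def tiny_roiset():
    """Six well-separated ROIs, one per network, on a compact grid."""
    entries = [
        ("dmn_a", "default_mode", -18.0, -18.0, 0.0),
        ("ecn_a", "executive_control", 18.0, -18.0, 0.0),
        ("sal_a", "salience", -18.0, 18.0, 0.0),
        ("smn_a", "sensorimotor", 18.0, 18.0, 0.0),
        ("aud_a", "auditory", -18.0, 0.0, 16.0),
        ("vis_a", "visual", 18.0, 0.0, 16.0),
    ]
    return RoiSet(tuple(Roi(n, net, (x, y, z), radius=5.0) for n, net, x, y, z in entries))


def make_run(data, tr=2.0, mask=None, motion=None, affine=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    if motion is None:
        motion = np.zeros((data.shape[3], 6))
    kwargs = {} if affine is None else {"affine": affine}
    return BoldRun(data=data, tr=tr, mask=mask, motion=motion, **kwargs)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
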