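"""Shared fixtures: small synthetic cohorts and trained-model fixtures.

Heavier fixtures are session-scoped so expensive training runs once and
is reused across tests.
"""

import numpy as np
import pytest

from cminr import synthetic as syn
from cminr.meta import case_from_subject
from cminr.prior import PriorNet, train_prior
from cminr.seeding import child_seed


@pytest.fixture(scope="session")
def small_cohort():
    """Three 16x16x8 subjects with 4 motion bins and known DVFs."""
    return syn.generate_cohort(
        3,
        syn.default_phantom_spec((16, 16, 8)),
        syn.MotionModel((0.3, 0.6, 1.2), 5.0, 4),
        syn.PhaseMapSpec(),
        syn.NoiseSpec(),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_case(small_cohort):
    """A preprocessed registration case (bin 2, 13 spokes) with truth."""
    return case_from_subject(small_cohort[0], 2, n_spokes=13,
                             samples_per_spoke=32, theta0_seed=7)


@pytest.fixture(scope="session")
def trained_prior(small_cohort):
    """A briefly-trained prior net on the small cohort (shared fixture)."""
    net = PriorNet(base_channels=8, seed=child_seed(42, "prior"))
    net, history = train_prior(
        net, small_cohort, epochs=80, lr=2e-3, n_spokes_range=(8, 13),
        samples_per_spoke=32, seed=child_seed(42, "train-prior"),
    )
    return net, history


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of scalar-valued f() w.r.t. array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
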