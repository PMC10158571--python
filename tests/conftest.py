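import numpy as np
import pytest

from natisc.config import Condition, NetworkSpec, SimulationConfig, default_couplings


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest sensible study: 2 networks x 2 parcels, short runs."""
    nets = (NetworkSpec("language", 2, 8), NetworkSpec("tom", 2, 8))
    conds = (
        Condition("story", "+Lang+ToM"),
        Condition("animated_film", "-Lang+ToM"),
        Condition("expository_text", "+Lang-ToM"),
        Condition("rest", "rest"),
    )
    return SimulationConfig(
        n_subjects=8,
        n_timepoints=120,
        networks=nets,
        conditions=conds,
        coupling=default_couplings(nets, conds),
        grid_shape=(8, 8, 4),
        seed=42,
    )


@pytest.fixture
def isc_like_table(rng):
    """Balanced long-format ISC table simulated directly from a mixed model
    with every variance component strictly positive."""
    import pandas as pd

    n_part, n_froi, n_cond = 16, 6, 6
    b_part = rng.normal(0, 0.15, n_part)
    b_froi = rng.normal(0, 0.10, n_froi)
    b_cond = rng.normal(0, 0.12, n_cond)
    s_net = rng.normal(0, 0.08, n_part)
    s_typ = rng.normal(0, 0.10, n_part)
    s_int = rng.normal(0, 0.09, n_part)
    rows = []
    for i in range(n_part):
        for f in range(n_froi):
            net = "language" if f < 3 else "tom"
            for c in range(n_cond):
                ctype = "+Lang+ToM" if c < 3 else "-Lang+ToM"
                xn = -0.5 if net == "language" else 0.5
                xt = -0.5 if c < 3 else 0.5
                z = (
                    0.2 + 0.1 * xn - 0.05 * xt + 0.15 * xn * xt
                    + b_part[i] + b_froi[f] + b_cond[c]
                    + s_net[i] * xn + s_typ[i] * xt + s_int[i] * xn * xt
                    + rng.normal(0, 0.12)
                )
                rows.append(
                    dict(
                        participant=i, froi=f"f{f}", network=net,
                        condition=f"c{c}", condition_type=ctype, z=z,
                    )
                )
    return pd.DataFrame(rows)
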