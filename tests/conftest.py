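import numpy as np
import pytest

import barrierscreen as bs


@pytest.fixture(scope="session")
def toy():
    """Small toy system: 8 residues, 3 inside the active-site shell."""
    return bs.make_toy_system(bs.ToySystemSpec(n_residues=8, n_active=3, seed=7))


@pytest.fixture(scope="session")
def toy_clash():
    """Toy system with position 11 walled in so side chains beyond CB clash."""
    return bs.make_toy_system(
        bs.ToySystemSpec(n_residues=8, n_active=3, seed=7,
                         clash_positions=frozenset({11}))
    )


def make_context(system, gt, layer_radius=float("inf"), n_intermediate=10, **surface_kw):
    """Screening context + settings for a toy system and programmed truth."""
    surface = bs.make_surface(
        gt,
        x1_es=system.rc.measure(system.es),
        x1_ge=system.rc.measure(system.ge),
        **surface_kw,
    )
    ctx = bs.ScreeningContext(
        wt_ge_opt=system.ge, wt_es_prime_opt=system.es, rc=system.rc,
        surface=surface, rules=system.rules,
    )
    settings = bs.ScreenSettings(n_intermediate=n_intermediate, layer_radius=layer_radius)
    return ctx, settings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
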