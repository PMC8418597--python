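import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210804)


@pytest.fixture
def noiseless_case():
    """Noiseless depth-0 phantom with surface TBR exactly 2."""
    from fgs_tbr.phantom import PhantomConfig, render_phantom

    cfg = PhantomConfig(background_sd=0.0, shot_noise=False, tbr_surface=2.0, seed=7)
    return render_phantom(cfg).as_case("noiseless")


@pytest.fixture
def noisy_case_factory():
    """Factory for noisy phantoms with configurable contrast/depth/seed."""
    from fgs_tbr.phantom import PhantomConfig, render_phantom

    def make(tbr_surface=3.0, depth_mm=0.0, seed=0, cohort="ANGIO", **kw):
        cfg = PhantomConfig(
            tbr_surface=tbr_surface,
            tumor_depth_mm=depth_mm,
            seed=seed,
            cohort=cohort,
            **kw,
        )
        return render_phantom(cfg).as_case(f"case{seed}")

    return make
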