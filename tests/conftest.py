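import numpy as np
import pytest

from spherenf import (
    AnalysisTemplate,
    DelayParams,
    FiringParams,
    LinearizationContext,
    build_icosphere,
)


@pytest.fixture(scope="session")
def bautin_template() -> AnalysisTemplate:
    """Kernel/delay family in which the n=0 Hopf turns from super- to
    subcritical as the firing threshold grows."""
    return AnalysisTemplate(sigma1=1.0, sigma2=0.5, delay=DelayParams(3.0, 1.0))


@pytest.fixture(scope="session")
def sharp_kernel_context() -> LinearizationContext:
    """Regime with a narrow kernel whose only unstable pair has degree 4."""
    return LinearizationContext.from_lumped_gains(
        29.50, -51.38, (2.0 / 9.0, 1.0 / 6.0), DelayParams(3.0, 0.8), n_max=5
    )


@pytest.fixture(scope="session")
def steep_firing() -> FiringParams:
    return FiringParams(1.0, 8.0, 0.0)


@pytest.fixture(scope="session")
def mesh_level2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def mesh_level3():
    return build_icosphere(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
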