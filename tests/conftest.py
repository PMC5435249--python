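import numpy as np
import pytest

from slopepower import CovariateSpec, DesignSpec, EffectSpec, make_design


@pytest.fixture
def balanced_design():
    """The canonical balanced reference design: delta=0.5, unit covariate variances."""
    return make_design(delta=0.5, tau1_sq=1.0, tau2_sq=1.0, n1=67, n2=67)


@pytest.fixture
def gingivitis_design():
    """Worked-example design: two gingivitis treatments, pretreatment index as covariate."""
    return DesignSpec(
        effect=EffectSpec(beta11=0.8502, beta12=0.4008, sigma2=0.04),
        covariates=CovariateSpec(tau1_sq=0.0646, tau2_sq=0.0526),
        n1=74,
        n2=64,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
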