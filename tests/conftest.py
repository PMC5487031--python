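import pytest
from hypothesis import settings

from ednaqpcr import QuantificationContext, ReplicateResult, StandardCurve

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def published_curve() -> StandardCurve:
    """Calibration curve with the published slope/intercept for the signal
    crayfish assay (efficiency 95.8%)."""
    return StandardCurve(assay_id="Paclen", slope=-3.427, intercept=39.34,
                         r_squared=0.998, n_points=18, dynamic_range=(5.0, 5e5))


@pytest.fixture
def norwegian_ctx() -> QuantificationContext:
    """5 L filtered, 200 µL eluate, 2 µL template: the 2+2 dilution design."""
    return QuantificationContext(V_e=200.0, V_r=2.0, V_w=5.0, scheme="norwegian")


@pytest.fixture
def danish_ctx() -> QuantificationContext:
    """1 L filtered, 5 µL template of a 200 µL eluate: 4 undiluted replicates."""
    return QuantificationContext(V_e=200.0, V_r=5.0, V_w=1.0, scheme="danish")


def well(ct, sample="S1", assay="A1", dilution=1, role="unknown"):
    return ReplicateResult(sample_id=sample, assay_id=assay,
                           dilution_factor=dilution, ct=ct, role=role)


@pytest.fixture
def make_well():
    return well
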