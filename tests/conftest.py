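import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swallowpfas import datasets
from swallowpfas.model import MeasuredValue, SampleRecord

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return datasets.default_registry()


@pytest.fixture(scope="session")
def dl_table():
    return datasets.default_detection_limits()


@pytest.fixture(scope="session")
def matrix_constants():
    return datasets.default_matrix_constants()


@pytest.fixture
def make_sample(dl_table):
    """Factory: build a SampleRecord from an analyte -> (value, detected) map."""

    def _make(
        values,
        sample_id="s1",
        site="SiteA",
        region="North",
        matrix="nestling",
        year=2021,
        **kwargs,
    ):
        measurements = {}
        for analyte, spec in values.items():
            if isinstance(spec, tuple):
                value, detected = spec
            else:
                value, detected = spec, True
            dl = dl_table.lookup(analyte, matrix, year)
            measurements[analyte] = MeasuredValue(
                value=value if detected else None,
                detected=detected,
                dl_used=dl,
            )
        if matrix == "nestling" and "age_days" not in kwargs:
            kwargs["age_days"] = 12.0
        return SampleRecord(
            sample_id=sample_id, site=site, region=region, matrix=matrix,
            year=year, measurements=measurements, **kwargs,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240910)
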