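import io

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pgxrev.allele_db import load_allele_definitions


TINY_DEFS = """\
# two-gene toy database
gene\tallele\tvariants\tfunction
GENEA\t*1\t\tnormal function
GENEA\t*2\tchr1:100:G:A\tno function
GENEA\t*2.001\tchr1:100:G:A\t
GENEA\t*3\tchr1:200:C:T\t
GENEA\t*5\tchr1:100:G:A;chr1:300:T:C\t
GENEB\t*1\t\t
GENEB\t*2\tchr2:50:A:G\t
"""


@pytest.fixture
def tiny_db():
    """Small database: GENEA has *5 extending *2, GENEB minimal."""
    return load_allele_definitions(io.StringIO(TINY_DEFS), "1.0")


@pytest.fixture
def default_function_table():
    from pgxrev.data import load_default_function_table

    return load_default_function_table()


@pytest.fixture
def statin_table():
    from pgxrev.data import load_statin_recommendations

    return load_statin_recommendations()
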