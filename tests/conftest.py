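import pytest

from vitd_cea import base_case, base_case_analysis


@pytest.fixture(scope="session")
def params():
    """Bundled base-case parameter set."""
    return base_case()


@pytest.fixture(scope="session")
def base_result(params):
    """Headline incremental analysis of the base case."""
    return base_case_analysis(params)
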