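import pytest

from cosolvency.datasets import load_smt_mecn_etoh
from cosolvency.solution import SolutionThermodynamics


@pytest.fixture(scope="session")
def smt_table():
    """The packaged 21×9 SMT solubility grid."""
    return load_smt_mecn_etoh()


@pytest.fixture(scope="session")
def smt_solution(smt_table):
    """Fitted solution thermodynamics for the packaged grid."""
    return SolutionThermodynamics(smt_table).fit()
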