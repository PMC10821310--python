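import pytest

from esccea import CostEffectivenessModel, make_config_fixture
from esccea.engine import run_base_case


@pytest.fixture(scope="session")
def overall_config():
    return make_config_fixture("overall")


@pytest.fixture(scope="session")
def overall_base(overall_config):
    return run_base_case(overall_config)


@pytest.fixture(scope="session")
def all_strata_base():
    return {s: CostEffectivenessModel.from_tables(s).fit()
            for s in ("overall", "cps_1_to_10", "cps_ge_10")}
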