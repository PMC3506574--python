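import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from truncvar.pipeline import annotate_files
from truncvar.synthetic import SyntheticSpec, generate_corpus

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default synthetic corpus (seed 42), generated once per session."""
    out = tmp_path_factory.mktemp("corpus")
    paths = generate_corpus(SyntheticSpec(seed=42), out)
    return paths


@pytest.fixture(scope="session")
def truth(corpus) -> pd.DataFrame:
    return pd.read_csv(corpus["truth"], sep="\t")


@pytest.fixture(scope="session")
def annotation(corpus) -> pd.DataFrame:
    """Pipeline output over the session corpus."""
    return annotate_files(corpus["gff3"], corpus["fasta"], corpus["vcf"],
                          corpus["domains"], corpus["structures"])
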