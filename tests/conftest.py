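import pandas as pd
import pytest

from pepsilico.cleavage import default_gi_enzymes
from pepsilico.motifs import default_motif_db
from pepsilico.physchem import _data_path

#: The five antioxidative validation peptides.
PANEL = ["RALGFDFRR", "RHTPFFKG", "RQMSLLLRR", "RLQLLARF", "KADSLISGAAQAVYNKF"]


@pytest.fixture(scope="session")
def gi_enzymes():
    return list(default_gi_enzymes())


@pytest.fixture(scope="session")
def motif_db():
    return default_motif_db()


def _load(name: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(name), sep="\t", comment="#")


@pytest.fixture(scope="session")
def expected_digests() -> pd.DataFrame:
    return _load("expected_digests.tsv")


@pytest.fixture(scope="session")
def expected_metrics() -> pd.DataFrame:
    return _load("expected_metrics.tsv")


@pytest.fixture(scope="session")
def expected_panels() -> pd.DataFrame:
    return _load("expected_panels.tsv")


@pytest.fixture(scope="session")
def expected_motif_scan() -> pd.DataFrame:
    return _load("expected_motif_scan.tsv")


@pytest.fixture(scope="session")
def screened_peptides_path():
    return _data_path("peptides_screened.tsv")
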