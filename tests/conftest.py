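import pytest

from globinkit import foldmap, synthdata
from globinkit.seqio import Alignment


@pytest.fixture(scope="session")
def default_fold():
    return foldmap.default_reference_fold()


@pytest.fixture(scope="session")
def reference_record():
    return foldmap.default_reference_sequence()


@pytest.fixture(scope="session")
def reference_mapping(default_fold, reference_record):
    """Fold mapping of the reference against itself (identity projection)."""
    aln = Alignment([reference_record])
    return foldmap.build_fold_mapping(aln, default_fold)[reference_record.id]


@pytest.fixture(scope="session")
def study_family():
    """The shipped study-shaped dataset: 187 globins, 14 planted deviants."""
    return synthdata.simulate_family(synthdata.default_family_config(seed=0))
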