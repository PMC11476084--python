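import pytest

from palb2prev.acmg_engine import ThresholdConfig, classify_all
from palb2prev.io_formats import partition_by_quality
from palb2prev.synthetic_data import TOY_TRANSCRIPT, make_paper_fixtures
from palb2prev.variant_model import TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    """The packaged fixture tables emulating the published database analysis."""
    return make_paper_fixtures()


@pytest.fixture(scope="session")
def kept_records(bundle):
    """Merged fixture records surviving the gnomAD-style quality filters."""
    kept, _ = partition_by_quality(bundle.all_records())
    return kept


@pytest.fixture(scope="session")
def classifications(bundle, kept_records):
    return classify_all(kept_records, bundle.transcript, bundle.thresholds)


@pytest.fixture(scope="session")
def toy_transcript():
    return TOY_TRANSCRIPT


@pytest.fixture(scope="session")
def two_exon_transcript():
    """Two exons of 200 + 100 nt, fully coding; the only junction is at 200."""
    return TranscriptModel(exon_lengths=(200, 100), cds_start_offset=0, cds_end_offset=300)


@pytest.fixture(scope="session")
def default_thresholds():
    return ThresholdConfig()
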