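import pytest

from ddsim.corpus_io import ReviewCorpus, ReviewRecord


@pytest.fixture
def three_row_corpus():
    return ReviewCorpus(
        [
            ReviewRecord("A", side_effects="dizzy", comments="tired at night"),
            ReviewRecord("A", side_effects="rash", comments="mild rash"),
            ReviewRecord("B", side_effects="nausea", comments="severe nausea"),
        ]
    )
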