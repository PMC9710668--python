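import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from alnmark import Alignment, SequenceRecord, read_fasta

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AA_GAP = "ACDEFGHIKLMNPQRSTVWY-"


@pytest.fixture
def toy_aln() -> Alignment:
    """Two-record toy alignment with a gap and parseable identities."""
    return read_fasta(
        ">sp|P12345|TOY1 Homo sapiens\nAC-GT\n>NP_000001.1 Mus musculus\nACAGT\n"
    )


def make_alignment(rows: list[str], headers: list[str] | None = None) -> Alignment:
    """Build an Alignment directly from gapped strings."""
    headers = headers or [f"seq{i}" for i in range(len(rows))]
    records = tuple(
        SequenceRecord(header=h, label=h, letters=row, alphabet="protein")
        for h, row in zip(headers, rows)
    )
    return Alignment(records=records)


gapped_letters = st.text(alphabet=AA_GAP, min_size=1, max_size=60)


@st.composite
def small_alignments(draw):
    """Random rectangular alignments, up to 10 sequences x 50 columns."""
    n_cols = draw(st.integers(min_value=1, max_value=50))
    n_rows = draw(st.integers(min_value=1, max_value=10))
    rows = [
        draw(st.text(alphabet=AA_GAP, min_size=n_cols, max_size=n_cols))
        for _ in range(n_rows)
    ]
    return make_alignment(rows)
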