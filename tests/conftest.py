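import pytest

from bcrflow.airr_io import Rearrangement, Repertoire


@pytest.fixture
def make_rec():
    """Factory for rearrangement records with sensible defaults."""

    def _make(
        sid,
        alignment="ACGT" * 8,
        junction="TGTGCGAGAGGG",
        v="IGHV1-2*01",
        j="IGHJ4*01",
        copies=1,
        productive=True,
        **kw,
    ):
        return Rearrangement(
            sequence_id=sid,
            v_call=v,
            d_call="IGHD3-10*01",
            j_call=j,
            junction=junction,
            junction_length=len(junction),
            productive=productive,
            duplicate_count=copies,
            sequence_alignment=alignment,
            germline_alignment=kw.pop("germline", alignment),
            **kw,
        )

    return _make


@pytest.fixture
def make_repertoire(make_rec):
    def _make(specs):
        return Repertoire(records=[make_rec(**s) for s in specs])

    return _make
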