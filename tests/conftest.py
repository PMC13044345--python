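import pytest

from msep.corpus import Sentence


def make_sentence(text: str, sent_id: str = "s0", doc_type: str = "Other",
                  patient_id: str = "p0", doc_id: str = "d0") -> Sentence:
    return Sentence(
        sent_id=sent_id, doc_id=doc_id, patient_id=patient_id,
        doc_type=doc_type, text=text, span=(0, len(text)),
    )


@pytest.fixture
def sent_factory():
    counter = {"n": 0}

    def make(text: str, **kw) -> Sentence:
        counter["n"] += 1
        kw.setdefault("sent_id", f"s{counter['n']}")
        return make_sentence(text, **kw)

    return make
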