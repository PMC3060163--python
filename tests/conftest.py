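import pytest

from songsyntax.corpus import Alphabet, Corpus


def make_corpus(*strings: str) -> Corpus:
    """Single-character-token corpus from literal strings."""
    seqs = [list(s) for s in strings]
    seen: dict[str, None] = {}
    for s in seqs:
        for t in s:
            seen.setdefault(t, None)
    return Corpus(seqs, Alphabet(tuple(seen)))


@pytest.fixture
def ab_corpus() -> Corpus:
    return make_corpus("AAB", "AB", "ABB", "AAAB")
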