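"""Symbol-sequence corpora: data model, text I/O, stream segmentation.

A corpus is an ordered collection of syllable sequences over a finite
alphabet.  Two reserved tokens exist: ``s`` (sequence start) and ``e``
(sequence end); they label the virtual start/end states of the transition
models and never appear inside data sequences.

The *non-repeat* form of a sequence collapses each maximal run of a
syllable to a single (symbol, repeat_count) pair, e.g. ``ECCDDFBBGBAA``
becomes ``E(1) C(2) D(2) F(1) B(2) G(1) B(1) A(2)``.  Expanding the pairs
recovers the original sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

START_TOKEN = "s"
END_TOKEN = "e"
RESERVED_TOKENS = frozenset({START_TOKEN, END_TOKEN})


class CorpusError(ValueError):
    """Raised for malformed corpora or corpus files."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of distinct syllable tokens (start/end excluded)."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise CorpusError("alphabet tokens must be unique")
        bad = RESERVED_TOKENS.intersection(self.symbols)
        if bad:
            raise CorpusError(f"reserved token(s) {sorted(bad)} not allowed in alphabet")

    def __contains__(self, token: str) -> bool:
        return token in self.symbols

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class Corpus:
    """List of non-empty symbol sequences over a shared alphabet."""

    sequences: list[list[str]]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        symset = set(self.alphabet.symbols)
        for i, seq in enumerate(self.sequences):
            if not seq:
                raise CorpusError(f"sequence {i} is empty")
            for tok in seq:
                if tok in RESERVED_TOKENS:
                    raise CorpusError(f"reserved token {tok!r} inside sequence {i}")
                if tok not in symset:
                    raise CorpusError(f"token {tok!r} in sequence {i} not in alphabet")

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Corpus)
            and self.sequences == other.sequences
            and self.alphabet == other.alphabet
        )


@dataclass
class NonRepeatCorpus:
    """Run-length-encoded corpus: sequences of (symbol, repeat_count) pairs."""

    sequences: list[list[tuple[str, int]]]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        for i, seq in enumerate(self.sequences):
            for j, (sym, cnt) in enumerate(seq):
                if cnt < 1:
                    raise CorpusError(f"repeat count < 1 at sequence {i}")
                if j > 0 and seq[j - 1][0] == sym:
                    raise CorpusError(f"consecutive identical symbols in non-repeat sequence {i}")

    def expand(self) -> Corpus:
        """Invert the run-length encoding."""
        seqs = [[sym for sym, cnt in seq for _ in range(cnt)] for seq in self.sequences]
        return Corpus(seqs, self.alphabet)


@dataclass
class AnnotatedStream:
    """Time-ordered (symbol, onset_s, offset_s) events, non-overlapping."""

    events: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for sym, on, off in self.events:
            if off < on:
                raise CorpusError(f"event {sym!r}: offset {off} before onset {on}")
        onsets = [on for _, on, _ in self.events]
        if onsets != sorted(onsets):
            raise CorpusError("events not sorted by onset")


def _infer_alphabet(sequences: Iterable[Sequence[str]]) -> Alphabet:
    seen: dict[str, None] = {}
    for seq in sequences:
        for tok in seq:
            seen.setdefault(tok, None)
    return Alphabet(tuple(seen))


def _parse_line(line: str, dialect: str) -> list[str]:
    if dialect == "tokens":
        return line.split()
    if dialect == "chars":
        return list(line.strip())
    raise CorpusError(f"unknown dialect {dialect!r}")


def read_corpus(path: str | Path, dialect: str = "chars") -> Corpus:
    """Read a one-sequence-per-line text corpus.

    ``dialect="chars"`` treats each non-space character as a token;
    ``dialect="tokens"`` splits on whitespace.  Blank lines are skipped.
    The alphabet is inferred in first-appearance order.
    """
    text = Path(path).read_text(encoding="utf-8")
    sequences: list[list[str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        seq = _parse_line(line, dialect)
        for tok in seq:
            if tok in RESERVED_TOKENS:
                raise CorpusError(f"reserved token {tok!r} on line {lineno}")
        sequences.append(seq)
    if not sequences:
        raise CorpusError("empty corpus")
    return Corpus(sequences, _infer_alphabet(sequences))


def write_corpus(corpus: Corpus, path: str | Path, dialect: str = "chars") -> None:
    """Write a corpus as one sequence per line; round-trips with read_corpus."""
    if len(corpus.alphabet) == 0:
        raise CorpusError("cannot write corpus with empty alphabet")
    lines = []
    for seq in corpus.sequences:
        if dialect == "chars":
            for tok in seq:
                if len(tok) != 1:
                    raise CorpusError(f"multi-char token {tok!r} incompatible with chars dialect")
            lines.append("".join(seq))
        elif dialect == "tokens":
            lines.append(" ".join(seq))
        else:
            raise CorpusError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_stream(path: str | Path) -> AnnotatedStream:
    """Read a 3-column TSV (symbol, onset_s, offset_s) annotated stream."""
    events = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        sym, on, off = line.split("\t")
        events.append((sym, float(on), float(off)))
    return AnnotatedStream(events)


def segment_stream(
    stream: AnnotatedStream,
    song_symbols: set[str],
    gap_threshold: float = 0.2,
    start_symbol: str | None = None,
) -> Corpus:
    """Cut an annotated event stream into song sequences.

    Maximal runs of song symbols whose inter-event gaps (previous offset to
    next onset) are strictly below ``gap_threshold`` form candidate
    sequences; any non-song event ends the current run.  If a
    ``start_symbol`` is given, each candidate is additionally split
    immediately before every occurrence of it that does not follow another
    occurrence — a candidate with k non-continuous start syllables in its
    interior yields k+1 sequences.
    """
    if gap_threshold <= 0:
        raise CorpusError("gap_threshold must be positive")
    if start_symbol is not None and start_symbol not in song_symbols:
        raise CorpusError(f"start symbol {start_symbol!r} not in song symbols")

    runs: list[list[str]] = []
    current: list[str] = []
    prev_offset: float | None = None
    for sym, on, off in stream.events:
        if sym not in song_symbols:
            if current:
                runs.append(current)
                current = []
            prev_offset = None
            continue
        if current and prev_offset is not None and (on - prev_offset) >= gap_threshold:
            runs.append(current)
            current = []
        current.append(sym)
        prev_offset = off
    if current:
        runs.append(current)

    sequences: list[list[str]] = []
    for run in runs:
        if start_symbol is None:
            sequences.append(run)
            continue
        pieces: list[list[str]] = [[]]
        for i, sym in enumerate(run):
            if sym == start_symbol and i > 0 and run[i - 1] != start_symbol and pieces[-1]:
                pieces.append([])
            pieces[-1].append(sym)
        sequences.extend(p for p in pieces if p)
    if not sequences:
        raise CorpusError("segmentation produced no sequences")
    return Corpus(sequences, _infer_alphabet(sequences))


def to_non_repeat(corpus: Corpus) -> NonRepeatCorpus:
    """Run-length encode every sequence (repeats collapsed, counts kept)."""
    out: list[list[tuple[str, int]]] = []
    for seq in corpus.sequences:
        pairs: list[tuple[str, int]] = []
        for tok in seq:
            if pairs and pairs[-1][0] == tok:
                pairs[-1] = (tok, pairs[-1][1] + 1)
            else:
                pairs.append((tok, 1))
        out.append(pairs)
    return NonRepeatCorpus(out, corpus.alphabet)
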