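"""Evaluation statistics for syllable-sequence corpora.

Three statistics summarize a corpus: per-syllable repeat-number
distributions (lengths of maximal runs), N-gram distributions for
N = 2..7, and step probabilities (probability of seeing a syllable at
step t from the sequence start; for the end symbol, the CDF of sequence
length).  Two corpora are compared per statistic with the maximum
normalized difference

    d = max_i |P1(i) - P2(i)| / max(max_i P1(i), max_i P2(i)),

which lies in [0, 1].  Because a finite corpus cannot yield d = 0 even
against a perfect model, a split-half benchmark gives the noise floor: the
corpus is randomly halved 500 times and the 0.95 quantile of each
statistic's d across splits is the value a good model should reach.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, END_TOKEN, to_non_repeat

NGRAM_RANGE = tuple(range(2, 8))
PMF_TOL = 1e-9


@dataclass
class RepeatDistribution:
    symbol: str
    pmf: dict[int, float]

    def __post_init__(self) -> None:
        _check_pmf(self.pmf.values())


@dataclass
class NgramDistribution:
    N: int
    pmf: dict[str, float]

    def __post_init__(self) -> None:
        _check_pmf(self.pmf.values())


@dataclass
class StepProbabilities:
    """Per-symbol P(symbol at step t), t = 1..T, plus the end curve.

    ``end[t-1]`` is the probability that a sequence has ended before step
    t, i.e. the CDF of sequence length evaluated at t - 1.
    """

    T: int
    curves: dict[str, np.ndarray]
    end: np.ndarray

    def __post_init__(self) -> None:
        total = self.end.copy()
        for c in self.curves.values():
            total = total + c
        if not np.allclose(total, 1.0, atol=PMF_TOL):
            raise ValueError("step probabilities do not normalize per step")
        if np.any(np.diff(self.end) < -PMF_TOL):
            raise ValueError("end curve must be non-decreasing")


@dataclass
class DistributionSet:
    repeat: dict[str, RepeatDistribution]
    ngram: dict[int, NgramDistribution]
    step: StepProbabilities


@dataclass
class ComparisonReport:
    """d-values per statistic key, optionally with split-half benchmarks.

    Keys are ``repeat:<sym>``, ``ngram:<N>``, ``step:<sym>`` and ``step:e``.
    """

    d_values: dict[str, float]
    benchmarks: dict[str, float] = field(default_factory=dict)

    def exceeds_benchmark(self) -> dict[str, bool]:
        return {
            k: d > self.benchmarks[k]
            for k, d in self.d_values.items()
            if k in self.benchmarks
        }


def _check_pmf(values) -> None:
    vals = np.fromiter(values, dtype=float)
    if np.any(vals < -PMF_TOL):
        raise ValueError("negative probability")
    if abs(vals.sum() - 1.0) > PMF_TOL:
        raise ValueError(f"pmf sums to {vals.sum()}, not 1")


def repeat_distributions(corpus: Corpus) -> dict[str, RepeatDistribution]:
    """Pmf of maximal-run lengths for every symbol of the corpus."""
    counts: dict[str, dict[int, int]] = {}
    for seq in to_non_repeat(corpus).sequences:
        for sym, cnt in seq:
            counts.setdefault(sym, {})
            counts[sym][cnt] = counts[sym].get(cnt, 0) + 1
    out = {}
    for sym in corpus.alphabet:
        if sym not in counts:
            continue
        total = sum(counts[sym].values())
        out[sym] = RepeatDistribution(
            sym, {n: c / total for n, c in sorted(counts[sym].items())}
        )
    return out


def ngram_distributions(
    corpus: Corpus, n_range: tuple[int, ...] = NGRAM_RANGE
) -> dict[int, NgramDistribution]:
    """Sliding-window N-gram pmfs within sequences (boundaries not crossed)."""
    out = {}
    for N in n_range:
        counts: dict[str, int] = {}
        for seq in corpus.sequences:
            for i in range(len(seq) - N + 1):
                gram = "".join(seq[i : i + N])
                counts[gram] = counts.get(gram, 0) + 1
        if not counts:
            warnings.warn(f"no sequence of length >= {N}; {N}-grams omitted")
            continue
        total = sum(counts.values())
        out[N] = NgramDistribution(N, {g: c / total for g, c in counts.items()})
    return out


def default_max_step(corpus: Corpus) -> int:
    """Default step horizon: 99th percentile of observed sequence lengths."""
    lengths = [len(s) for s in corpus.sequences]
    return max(1, int(np.percentile(lengths, 99)))


def step_probabilities(corpus: Corpus, T: int | None = None) -> StepProbabilities:
    """P(symbol at step t) for t = 1..T and the sequence-length CDF."""
    if T is None:
        T = default_max_step(corpus)
    if T < 1:
        raise ValueError("T must be >= 1")
    n = len(corpus.sequences)
    curves = {sym: np.zeros(T) for sym in corpus.alphabet}
    ended = np.zeros(T)
    for seq in corpus.sequences:
        for t in range(1, T + 1):
            if t <= len(seq):
                curves[seq[t - 1]][t - 1] += 1
            else:
                ended[t - 1] += 1
    for sym in curves:
        curves[sym] /= n
    return StepProbabilities(T, curves, ended / n)


def distribution_set(
    corpus: Corpus,
    n_range: tuple[int, ...] = NGRAM_RANGE,
    T: int | None = None,
) -> DistributionSet:
    return DistributionSet(
        repeat=repeat_distributions(corpus),
        ngram=ngram_distributions(corpus, n_range),
        step=step_probabilities(corpus, T),
    )


def d_value(P1: dict, P2: dict) -> float:
    """Maximum normalized difference between two pmfs (union support)."""
    support = set(P1) | set(P2)
    if not support:
        raise ValueError("both pmfs empty")
    a = np.array([P1.get(k, 0.0) for k in support])
    b = np.array([P2.get(k, 0.0) for k in support])
    denom = max(a.max(), b.max())
    if denom == 0:
        raise ValueError("both pmfs all-zero")
    return float(np.abs(a - b).max() / denom)


def _d_curve(c1: np.ndarray, c2: np.ndarray) -> float | None:
    denom = max(c1.max(), c2.max())
    if denom == 0:
        return None
    return float(np.abs(c1 - c2).max() / denom)


def _is_repeating(ds: DistributionSet, sym: str) -> bool:
    rd = ds.repeat.get(sym)
    return rd is not None and any(n > 1 for n in rd.pmf)


def compare(observed: DistributionSet, generated: DistributionSet) -> ComparisonReport:
    """d-value per statistic between two distribution sets.

    Repeat pmfs are compared only for symbols that repeat at least once in
    either corpus; a symbol absent from one side contributes its d against
    an empty (all-zero) pmf.
    """
    if set(observed.step.curves) != set(generated.step.curves):
        raise ValueError("mismatched alphabets")
    d: dict[str, float] = {}
    for sym in observed.step.curves:
        if _is_repeating(observed, sym) or _is_repeating(generated, sym):
            p1 = observed.repeat[sym].pmf if sym in observed.repeat else {}
            p2 = generated.repeat[sym].pmf if sym in generated.repeat else {}
            d[f"repeat:{sym}"] = d_value(p1, p2)
    for N in sorted(set(observed.ngram) & set(generated.ngram)):
        d[f"ngram:{N}"] = d_value(observed.ngram[N].pmf, generated.ngram[N].pmf)
    if observed.step.T != generated.step.T:
        raise ValueError("step probability horizons differ")
    for sym in observed.step.curves:
        dv = _d_curve(observed.step.curves[sym], generated.step.curves[sym])
        if dv is not None:
            d[f"step:{sym}"] = dv
    dv = _d_curve(observed.step.end, generated.step.end)
    if dv is not None:
        d[f"step:{END_TOKEN}"] = dv
    return ComparisonReport(d)


def compare_corpora(
    observed: Corpus,
    generated: Corpus,
    n_range: tuple[int, ...] = NGRAM_RANGE,
    T: int | None = None,
) -> ComparisonReport:
    """Convenience wrapper: build both DistributionSets (at the observed
    corpus's step horizon) and compare them."""
    if set(observed.alphabet.symbols) != set(generated.alphabet.symbols):
        # align alphabets: a generated corpus may drop rare symbols
        union = tuple(dict.fromkeys(list(observed.alphabet) + list(generated.alphabet)))
        from .corpus import Alphabet

        observed = Corpus(observed.sequences, Alphabet(union))
        generated = Corpus(generated.sequences, Alphabet(union))
    if T is None:
        T = default_max_step(observed)
    return compare(
        distribution_set(observed, n_range, T),
        distribution_set(generated, n_range, T),
    )


def benchmark(
    corpus: Corpus,
    n_splits: int = 500,
    quantile: float = 0.95,
    rng_seed: int | None = None,
    n_range: tuple[int, ...] = NGRAM_RANGE,
    T: int | None = None,
) -> dict[str, float]:
    """Split-half noise floor per statistic.

    Each split assigns every sequence independently with probability 0.5 to
    one of two groups (empty groups are redrawn); the benchmark is the
    empirical ``quantile`` of the d-values across splits.
    """
    if len(corpus.sequences) < 20:
        raise ValueError("benchmark needs a corpus of at least 20 sequences")
    rng = np.random.default_rng(rng_seed)
    if T is None:
        T = default_max_step(corpus)
    samples: dict[str, list[float]] = {}
    for _ in range(n_splits):
        while True:
            mask = rng.random(len(corpus.sequences)) < 0.5
            if mask.any() and not mask.all():
                break
        g1 = Corpus([s for s, m in zip(corpus.sequences, mask) if m], corpus.alphabet)
        g2 = Corpus([s for s, m in zip(corpus.sequences, mask) if not m], corpus.alphabet)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = compare(
                distribution_set(g1, n_range, T), distribution_set(g2, n_range, T)
            )
        for k, v in rep.d_values.items():
            samples.setdefault(k, []).append(v)
    return {k: float(np.quantile(v, quantile)) for k, v in samples.items()}


def cosine_similarity(x, y) -> float:
    """Centered cosine similarity of two vectors (equals Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero norm after centering")
    return float(np.dot(xc, yc) / (nx * ny))


def shuffle_mean_test(
    sample1, sample2, n_shuffles: int = 500, rng_seed: int | None = None
) -> float:
    """Two-tailed permutation p-value for a difference of means.

    Pools the samples, re-partitions at the original sizes ``n_shuffles``
    times, and reports the smoothed two-tailed fraction
    (b + 1) / (n_shuffles + 1) of shuffled |Δmean| at least as large as the
    observed one.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    observed = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pool)
        if abs(perm[: a.size].mean() - perm[a.size :].mean()) >= observed:
            hits += 1
    return (hits + 1) / (n_shuffles + 1)


def export_csv(ds: DistributionSet, path: str | Path) -> None:
    """Long-format CSV export: statistic, key, category, probability."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["statistic", "key", "category", "probability"])
        for sym, rd in ds.repeat.items():
            for n, p in rd.pmf.items():
                w.writerow(["repeat", sym, n, p])
        for N, nd in ds.ngram.items():
            for gram, p in nd.pmf.items():
                w.writerow(["ngram", N, gram, p])
        for sym, curve in ds.step.curves.items():
            for t, p in enumerate(curve, start=1):
                w.writerow(["step", sym, t, p])
        for t, p in enumerate(ds.step.end, start=1):
            w.writerow(["step", END_TOKEN, t, p])
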