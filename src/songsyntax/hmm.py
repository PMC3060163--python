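"""Discrete-emission HMM baseline with structural start and end states.

The model has ``n_states`` emitting states plus a start and an end state
that emit only their own (virtual) tokens: sequences begin by a draw from
the start distribution ``pi`` and terminate through per-state end
probabilities ``a_end`` (transitions start -> end and anything -> start
are structurally excluded), so each row satisfies
sum_j A[i, j] + a_end[i] = 1.  Training is Baum-Welch (EM) with
per-step scaling so likelihoods stay finite on long sequences; 20 random
restarts guard against local optima and the best log-likelihood wins.
Convergence is declared when the largest absolute change over all
transition and emission probabilities drops below ``tol``.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Alphabet, Corpus

_SCHEMA = "songsyntax-hmm"
_SCHEMA_VERSION = 1


class HmmError(ValueError):
    pass


@dataclass
class Hmm:
    alphabet: Alphabet
    pi: np.ndarray  # (K,) start -> state
    A: np.ndarray  # (K, K) state -> state
    a_end: np.ndarray  # (K,) state -> end
    B: np.ndarray  # (K, S) emission probabilities

    def __post_init__(self) -> None:
        K = self.pi.size
        if self.A.shape != (K, K) or self.a_end.shape != (K,):
            raise HmmError("inconsistent shapes")
        if self.B.shape != (K, len(self.alphabet)):
            raise HmmError("emission matrix shape mismatch")
        if abs(self.pi.sum() - 1) > 1e-6:
            raise HmmError("start distribution must sum to 1")
        rows = self.A.sum(axis=1) + self.a_end
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise HmmError("transition rows (incl. end) must sum to 1")
        if not np.allclose(self.B.sum(axis=1), 1.0, atol=1e-6):
            raise HmmError("emission rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.pi.size


def _encode(
    corpus: Corpus, alphabet: Alphabet | None = None
) -> tuple[dict[str, int], list[tuple[np.ndarray, float]]]:
    sym_idx = {s: i for i, s in enumerate(alphabet or corpus.alphabet)}
    agg: Counter = Counter(tuple(seq) for seq in corpus.sequences)
    try:
        data = [
            (np.array([sym_idx[t] for t in seq], dtype=int), float(c))
            for seq, c in agg.items()
        ]
    except KeyError as exc:
        raise HmmError(f"corpus symbol {exc} outside the model alphabet") from exc
    return sym_idx, data


def _forward_backward(hmm: Hmm, obs: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, end_gamma, loglik)."""
    T = obs.size
    K = hmm.n_states
    alpha = np.empty((T, K))
    scale = np.empty(T)
    alpha[0] = hmm.pi * hmm.B[:, obs[0]]
    scale[0] = alpha[0].sum()
    if scale[0] == 0:
        return None
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ hmm.A) * hmm.B[:, obs[t]]
        scale[t] = alpha[t].sum()
        if scale[t] == 0:
            return None
        alpha[t] /= scale[t]
    p_end = alpha[T - 1] @ hmm.a_end
    if p_end == 0:
        return None
    loglik = np.log(scale).sum() + np.log(p_end)

    beta = np.empty((T, K))
    beta[T - 1] = hmm.a_end / p_end
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = hmm.B[:, obs[t + 1]] * beta[t + 1]
        beta[t] = (hmm.A @ w) / scale[t + 1]
        xi_sum += np.outer(alpha[t], w / scale[t + 1]) * hmm.A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    end_gamma = alpha[T - 1] * hmm.a_end / p_end
    return gamma, xi_sum, end_gamma, loglik


def _em_step(hmm: Hmm, data, sym_count: int):
    K = hmm.n_states
    pi_acc = np.zeros(K)
    A_acc = np.zeros((K, K))
    end_acc = np.zeros(K)
    B_acc = np.zeros((K, sym_count))
    occ_acc = np.zeros(K)
    total_ll = 0.0
    for obs, w in data:
        res = _forward_backward(hmm, obs)
        if res is None:
            return None
        gamma, xi_sum, end_gamma, ll = res
        total_ll += w * ll
        pi_acc += w * gamma[0]
        A_acc += w * xi_sum
        end_acc += w * end_gamma
        occ_acc += w * gamma.sum(axis=0)
        for t, o in enumerate(obs):
            B_acc[:, o] += w * gamma[t]
    pi_new = pi_acc / pi_acc.sum()
    denom = A_acc.sum(axis=1) + end_acc
    denom[denom == 0] = 1.0
    A_new = A_acc / denom[:, None]
    end_new = end_acc / denom
    occ_acc[occ_acc == 0] = 1.0
    B_new = B_acc / occ_acc[:, None]
    # guard rows that received no occupancy
    B_new[B_new.sum(axis=1) == 0] = 1.0 / sym_count
    return Hmm(hmm.alphabet, pi_new, A_new, end_new, B_new), total_ll


def train(
    corpus: Corpus,
    n_states: int,
    n_restarts: int = 20,
    tol: float = 1e-3,
    rng_seed: int | None = None,
    max_iter: int = 500,
    ll_history: list | None = None,
) -> tuple[Hmm, float]:
    """Baum-Welch training; returns the best model over restarts and its
    log-likelihood.  Restart seeds derive deterministically from
    ``rng_seed``; ``ll_history`` (if given) collects each restart's final
    log-likelihood."""
    if n_states < 1:
        raise HmmError("n_states must be >= 1")
    sym_idx, data = _encode(corpus)
    S = len(sym_idx)
    master = np.random.default_rng(rng_seed)
    best: tuple[Hmm, float] | None = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        hmm = _random_hmm(corpus.alphabet, n_states, S, rng)
        prev_ll = -np.inf
        for _ in range(max_iter):
            step = _em_step(hmm, data, S)
            if step is None:
                break
            new, ll = step
            if ll < prev_ll - 1e-8:
                raise RuntimeError("EM log-likelihood decreased")
            delta = max(
                np.abs(new.pi - hmm.pi).max(),
                np.abs(new.A - hmm.A).max(),
                np.abs(new.a_end - hmm.a_end).max(),
                np.abs(new.B - hmm.B).max(),
            )
            hmm, prev_ll = new, ll
            if delta < tol:
                break
        if ll_history is not None:
            ll_history.append(prev_ll)
        if np.isfinite(prev_ll) and (best is None or prev_ll > best[1]):
            best = (hmm, prev_ll)
    if best is None:
        raise HmmError("no restart produced a finite likelihood")
    return best


def _random_hmm(alphabet: Alphabet, K: int, S: int, rng) -> Hmm:
    pi = rng.dirichlet(np.ones(K))
    rows = rng.dirichlet(np.ones(K + 1), size=K)
    return Hmm(alphabet, pi, rows[:, :K], rows[:, K], rng.dirichlet(np.ones(S), size=K))


def log_likelihood(hmm: Hmm, corpus: Corpus) -> float:
    _, data = _encode(corpus, hmm.alphabet)
    total = 0.0
    for obs, w in data:
        res = _forward_backward(hmm, obs)
        if res is None:
            return -np.inf
        total += w * res[3]
    return total


def generate_hmm(
    hmm: Hmm, n: int, rng_seed: int | None = None, max_len: int = 1000
) -> Corpus:
    """Sample sequences: state walk as in the state models, with the
    syllable drawn from the state's emission distribution."""
    rng = np.random.default_rng(rng_seed)
    symbols = list(hmm.alphabet)
    pi_cum = np.cumsum(hmm.pi)
    row_cum = np.cumsum(np.hstack([hmm.A, hmm.a_end[:, None]]), axis=1)
    B_cum = np.cumsum(hmm.B, axis=1)
    K = hmm.n_states
    sequences = []
    truncated = 0
    for _ in range(n):
        seq: list[str] = []
        state = int(np.searchsorted(pi_cum, rng.random()))
        while True:
            if len(seq) >= max_len:
                truncated += 1
                break
            seq.append(symbols[int(np.searchsorted(B_cum[state], rng.random()))])
            nxt = int(np.searchsorted(row_cum[state], rng.random()))
            if nxt >= K:
                break
            state = nxt
        if seq:
            sequences.append(seq)
    if truncated:
        warnings.warn(f"{truncated}/{n} sequences truncated at max_len={max_len}")
    return Corpus(sequences, hmm.alphabet)


def length_pmf(hmm: Hmm, n_max: int) -> np.ndarray:
    """Exact pmf of the generated sequence length for L = 1..n_max."""
    out = np.empty(n_max)
    v = hmm.pi.copy()
    for L in range(1, n_max + 1):
        out[L - 1] = v @ hmm.a_end
        v = v @ hmm.A
    return out


def sweep_states(
    corpus: Corpus,
    state_counts: list[int],
    benchmarks: dict[str, float],
    n_generate: int = 10_000,
    n_restarts: int = 20,
    rng_seed: int | None = None,
):
    """Train at each state count, generate, and compare d-values.

    Returns {n_states: ComparisonReport} with the benchmarks attached."""
    from .distributions import ComparisonReport, compare_corpora

    out: dict[int, ComparisonReport] = {}
    for idx, k in enumerate(state_counts):
        hmm, _ = train(
            corpus, k, n_restarts=n_restarts, rng_seed=None if rng_seed is None else rng_seed + idx
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gen = generate_hmm(hmm, n_generate, rng_seed=rng_seed)
            rep = compare_corpora(corpus, gen)
        rep.benchmarks = dict(benchmarks)
        out[k] = rep
    return out


def save_hmm(hmm: Hmm, path: str | Path) -> None:
    doc = {
        "schema": _SCHEMA,
        "version": _SCHEMA_VERSION,
        "alphabet": list(hmm.alphabet.symbols),
        "pi": hmm.pi.tolist(),
        "A": hmm.A.tolist(),
        "a_end": hmm.a_end.tolist(),
        "B": hmm.B.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_hmm(path: str | Path) -> Hmm:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _SCHEMA or doc.get("version") != _SCHEMA_VERSION:
        raise HmmError(f"unsupported HMM schema in {path}")
    return Hmm(
        Alphabet(tuple(doc["alphabet"])),
        np.array(doc["pi"]),
        np.array(doc["A"]),
        np.array(doc["a_end"]),
        np.array(doc["B"]),
    )
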