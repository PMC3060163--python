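"""Morphing a derived POMM into a POMMA, and the non-adaptive alternative.

A POMM from the state-merging derivation carries an empirical
repeat-number pmf on every state.  ``morph_to_pomma`` replaces each
repeating state with one or two states with (possibly adaptive)
self-transitions chosen by the repeat-family escalation: a single
adaptive state, two serial states with one or two adaptive self-loops, or
two serial states with no self-loops for near-deterministic double
repeats.  Incoming transitions attach to the first replacement state and
both replacement states exit to the original successors, with the
probabilities rescaled so every outgoing row (self + forward + exits)
stays normalized — which preserves each replaced state's marginal
next-syllable distribution.

``build_pomm_with_repeats`` is the adaptation-free alternative: each
repeating state is replaced by its own single-syllable sub-POMM (trained
with the Baum-Welch machinery, which with one emission symbol is a POMM)
grown until the sub-model reproduces the state's repeat pmf.  It needs
more states than the POMMA wherever the repeat pmf is peaked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Alphabet, Corpus
from .distributions import RepeatDistribution, cosine_similarity
from .hmm import Hmm, length_pmf, train
from .models import END, START, ModelError, State, StateModel
from . import repeat_models


@dataclass
class MorphRecord:
    state: int
    family: str
    params: tuple[float, ...]
    similarity: float


def _is_repeating(st: State) -> bool:
    return st.repeat_pmf is not None and any(n > 1 for n in st.repeat_pmf)


def morph_to_pomma(
    pomm: StateModel,
    similarity_threshold: float = 0.95,
    rng_seed: int | None = None,
    report: list[MorphRecord] | None = None,
    benchmarks: dict[str, float] | None = None,
    benchmark_margin: float = 0.5,
) -> StateModel:
    """Replace every repeating state by its fitted adaptive construction.

    When split-half ``benchmarks`` of the observed corpus are given, the
    family escalation additionally requires each fitted repeat pmf to
    match the observed one with a d-value at or below
    ``benchmark_margin`` times the syllable's repeat benchmark: the model
    error must sit comfortably below the finite-sample noise floor, so
    that model error plus generation noise still reaches the benchmark."""
    states: dict[int, State] = {}
    trans: dict[tuple[int, int], float] = {}
    next_id = max(pomm.states) + 1

    for i, st in pomm.states.items():
        if i in (START, END):
            states[i] = State(i, None)
            for j, p in pomm.successors(i).items():
                trans[(i, j)] = p
            continue
        exits = pomm.successors(i)  # repeat states carry no self transitions
        if not _is_repeating(st):
            states[i] = State(i, st.emission)
            for j, p in exits.items():
                trans[(i, j)] = p
            continue
        observed = RepeatDistribution(st.emission, dict(st.repeat_pmf))
        d_ceiling = (benchmarks or {}).get(f"repeat:{st.emission}")
        if d_ceiling is not None:
            d_ceiling *= benchmark_margin
        try:
            res = repeat_models.escalate(
                observed, similarity_threshold, rng_seed, d_ceiling=d_ceiling
            )
        except repeat_models.FitError as exc:
            raise ModelError(f"state {i} ({st.emission}): {exc}") from exc
        if report is not None:
            report.append(MorphRecord(i, res.model.family, res.model.params, res.similarity))
        fam, params = res.model.family, res.model.params
        if fam == "single":
            p, alpha = params
            states[i] = State(i, st.emission, self_p=p, alpha=alpha)
            trans[(i, i)] = p
            for j, q in exits.items():
                trans[(i, j)] = (1.0 - p) * q
        else:
            second = next_id
            next_id += 1
            states[second] = State(second, st.emission)
            if fam == "pure_serial":
                (q12,) = params
                states[i] = State(i, st.emission)
                trans[(i, second)] = q12
                for j, q in exits.items():
                    trans[(i, j)] = (1.0 - q12) * q
                    trans[(second, j)] = q
            elif fam == "serial_one":
                p1, a1, p12 = params
                states[i] = State(i, st.emission, self_p=p1, alpha=a1)
                trans[(i, i)] = p1
                trans[(i, second)] = p12
                for j, q in exits.items():
                    trans[(i, j)] = (1.0 - p1 - p12) * q
                    trans[(second, j)] = q
            elif fam == "serial_two":
                p1, a1, p2, a2, p12 = params
                states[i] = State(i, st.emission, self_p=p1, alpha=a1)
                states[second] = State(second, st.emission, self_p=p2, alpha=a2)
                trans[(i, i)] = p1
                trans[(i, second)] = p12
                trans[(second, second)] = p2
                for j, q in exits.items():
                    trans[(i, j)] = (1.0 - p1 - p12) * q
                    trans[(second, j)] = (1.0 - p2) * q
            else:  # pragma: no cover
                raise ModelError(f"unknown family {fam!r}")

    # drop zero-probability entries (e.g. p12 fitted to exactly 0)
    trans = {k: p for k, p in trans.items() if p > 0}
    states = {
        i: st
        for i, st in states.items()
        if i in (START, END) or any(a == i or b == i for (a, b) in trans)
    }
    return StateModel(states, trans, pomm.alphabet)


def _repeat_training_corpus(st: State) -> tuple[Corpus, dict[int, float]]:
    """Weighted single-symbol corpus of the state's repeat runs."""
    alphabet = Alphabet((st.emission,))
    pmf = dict(st.repeat_pmf)
    # encode weights as multiplicities on a common denominator
    seqs = []
    for n, p in sorted(pmf.items()):
        mult = max(1, round(p * 10_000))
        seqs.extend([[st.emission] * n] * mult)
    return Corpus(seqs, alphabet), pmf


def build_pomm_with_repeats(
    pomm: StateModel,
    similarity_threshold: float = 0.95,
    max_substates: int = 8,
    rng_seed: int | None = None,
    n_restarts: int = 5,
) -> StateModel:
    """Replace repeating states with trained single-syllable sub-POMMs.

    The sub-model's state count grows from 1 until its analytic
    repeat-length pmf matches the observed one with cosine similarity at
    or above the threshold.  Incoming transitions are split over the
    sub-model's start distribution; each sub-state's end mass exits to the
    original successors."""
    states: dict[int, State] = {}
    trans: dict[tuple[int, int], float] = {}
    next_id = max(pomm.states) + 1
    redirect: dict[int, list[tuple[int, float]]] = {}  # old id -> [(new id, share)]
    internal: set[tuple[int, int]] = set()  # sub-model edges, exempt from re-routing

    for i, st in pomm.states.items():
        if i in (START, END):
            states[i] = State(i, None)
            for j, p in pomm.successors(i).items():
                trans[(i, j)] = p
            continue
        exits = pomm.successors(i)
        if not _is_repeating(st):
            states[i] = State(i, st.emission)
            for j, p in exits.items():
                trans[(i, j)] = p
            continue
        sub = _fit_sub_pomm(st, similarity_threshold, max_substates, rng_seed, n_restarts)
        K = sub.n_states
        ids = [i] + [next_id + k for k in range(K - 1)]
        next_id += K - 1
        for sid in ids:
            states[sid] = State(sid, st.emission)
        redirect[i] = [(ids[k], float(sub.pi[k])) for k in range(K) if sub.pi[k] > 0]
        for a in range(K):
            for b in range(K):
                if sub.A[a, b] > 0:
                    trans[(ids[a], ids[b])] = float(sub.A[a, b])
                    internal.add((ids[a], ids[b]))
            if sub.a_end[a] > 0:
                for j, q in exits.items():
                    trans[(ids[a], j)] = trans.get((ids[a], j), 0.0) + float(sub.a_end[a]) * q

    # route incoming transitions of replaced states through the sub-model starts
    routed: dict[tuple[int, int], float] = {}
    for (a, b), p in trans.items():
        targets = [(b, 1.0)] if (a, b) in internal else redirect.get(b, [(b, 1.0)])
        for bb, share in targets:
            routed[(a, bb)] = routed.get((a, bb), 0.0) + p * share
    # exit edges of replaced states may themselves point at replaced states;
    # drop any state left unreachable from the start (zero start-distribution share)
    reach = {START}
    frontier = [START]
    while frontier:
        u = frontier.pop()
        for (a, b) in routed:
            if a == u and b not in reach:
                reach.add(b)
                frontier.append(b)
    states = {i: s for i, s in states.items() if i in reach or i == END}
    routed = {(a, b): p for (a, b), p in routed.items() if a in states and (b in states or b == END)}
    # sub-model states may carry self-loops; mirror them in the state records
    states = {
        i: (
            s
            if i in (START, END)
            else State(i, s.emission, self_p=routed.get((i, i), 0.0))
        )
        for i, s in states.items()
    }
    return StateModel(states, routed, pomm.alphabet)


def _fit_sub_pomm(
    st: State,
    threshold: float,
    max_substates: int,
    rng_seed: int | None,
    n_restarts: int,
) -> Hmm:
    corpus, pmf = _repeat_training_corpus(st)
    n_max = max(pmf) + 2
    target = np.array([pmf.get(n, 0.0) for n in range(1, n_max + 1)])
    for k in range(1, max_substates + 1):
        hmm, _ = train(
            corpus,
            k,
            n_restarts=n_restarts,
            rng_seed=None if rng_seed is None else rng_seed + k,
        )
        fitted = length_pmf(hmm, n_max)
        if np.allclose(fitted, fitted[0]) or np.allclose(target, target[0]):
            sim = 1.0 if np.allclose(fitted, target, atol=1e-6) else 0.0
        else:
            sim = cosine_similarity(fitted, target)
        if sim >= threshold:
            return hmm
    raise ModelError(
        f"repeat pmf of state {st.id} not reproduced within {max_substates} sub-states"
    )
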