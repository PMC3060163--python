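"""Ground-truth fixture models and sampled corpora.

These generators define the study conditions for every test: a canonical
two-symbol, three-state POMM whose structure the state-merging derivation
must recover; random identifiable POMMs for structure-recovery
simulations; and a Bengalese-finch-like POMMA combining an adaptive
repeat state, a serial adaptive pair, a near-deterministic double-repeat
pair and a many-to-one syllable mapping.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .corpus import Alphabet
from .models import END, START, ModelError, State, StateModel


def example_s1() -> StateModel:
    """Canonical two-symbol POMM: states U ("1"), V ("2"), W ("1").

    The start always enters U; U always continues to V; V either ends or
    continues to W; W either ends or returns to V — every state has equal
    probabilities on its outgoing transitions.  Sequences are
    12, 121, 1212, ...; U and W carry symbol 1 with clearly different
    suffix distributions (U is never final), making the two 1-states
    identifiable for state merging."""
    U, V, W = 2, 3, 4
    states = {
        START: State(START, None),
        END: State(END, None),
        U: State(U, "1"),
        V: State(V, "2"),
        W: State(W, "1"),
    }
    trans = {
        (START, U): 1.0,
        (U, V): 1.0,
        (V, W): 0.5,
        (V, END): 0.5,
        (W, V): 0.5,
        (W, END): 0.5,
    }
    return StateModel(states, trans, Alphabet(("1", "2")))


def model_suffix_pmf(
    model: StateModel, state: int, max_len: int = 15, mass_tol: float = 1e-4
) -> dict[tuple, float]:
    """Analytic distribution of the next-symbol sequences following a state
    (truncated at ``max_len``; path mass below ``mass_tol`` is truncated
    early and pooled on its prefix)."""
    out: dict[tuple, float] = {}
    queue = deque([(state, (), 1.0)])
    while queue:
        cur, suffix, mass = queue.popleft()
        for j, p in model.successors(cur).items():
            m = mass * p
            if j == END:
                out[suffix] = out.get(suffix, 0.0) + m
                continue
            suf = suffix + (model.states[j].emission,)
            if len(suf) >= max_len or m < mass_tol:
                out[suf[:max_len]] = out.get(suf[:max_len], 0.0) + m
            else:
                queue.append((j, suf, m))
    return out


def _suffix_cosine(p1: dict, p2: dict) -> float:
    """Uncentered cosine of two suffix pmfs — the same measure state
    merging uses, so the identifiability check matches the derivation."""
    support = sorted(set(p1) | set(p2))
    a = np.array([p1.get(k, 0.0) for k in support])
    b = np.array([p2.get(k, 0.0) for k in support])
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def random_pomm(
    n_states: int,
    alphabet: Alphabet | tuple[str, ...],
    rng_seed: int | None = None,
    identifiable: bool = True,
    similarity_ceiling: float = 0.9,
    max_tries: int = 200,
) -> StateModel:
    """Random connected POMM over the alphabet.

    Transitions never connect two states with the same symbol (matching
    the structure the non-repeat derivation can produce) and the end state
    is reachable from everywhere.  With ``identifiable`` set, candidates
    whose same-symbol states have suffix-distribution cosine similarity at
    or above ``similarity_ceiling`` are rejected, so state merging has a
    recoverable target."""
    if not isinstance(alphabet, Alphabet):
        alphabet = Alphabet(tuple(alphabet))
    if n_states < len(alphabet):
        raise ModelError("need at least one state per symbol")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        model = _random_pomm_once(n_states, alphabet, rng)
        if model is None:
            continue
        if not identifiable:
            return model
        ok = True
        for sym in alphabet:
            ids = model.states_for_symbol(sym)
            pmfs = [model_suffix_pmf(model, i) for i in ids]
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    if _suffix_cosine(pmfs[a], pmfs[b]) >= similarity_ceiling:
                        ok = False
        if ok:
            return model
    raise ModelError("no identifiable random POMM found within max_tries")


def _random_pomm_once(n_states: int, alphabet: Alphabet, rng) -> StateModel | None:
    symbols = list(alphabet) + [
        str(rng.choice(list(alphabet))) for _ in range(n_states - len(alphabet))
    ]
    rng.shuffle(symbols)
    ids = list(range(2, 2 + n_states))
    states = {START: State(START, None), END: State(END, None)}
    for i, sym in zip(ids, symbols):
        states[i] = State(i, sym)
    # layered DAG: transitions only to later states or the end, so
    # sequences are at most n_states runs long and the end is always
    # reachable; cyclic toplogies can make sequences (and the derivation
    # tree) explode
    # Two structural requirements for recoverability by prefix-tree
    # merging: (a) a state's successors all carry distinct symbols (and so
    # do the start state's), so each observed prefix maps to exactly one
    # state and tree states never pool distinct generator states; (b) a
    # state's successors differ from its own symbol (non-repeat level).
    trans: dict[tuple[int, int], float] = {}
    for idx, i in enumerate(ids):
        allowed = [
            j for j in ids[idx + 1 :] if states[j].emission != states[i].emission
        ]
        rng.shuffle(allowed)
        succ: list[int] = []
        used_syms: set[str] = set()
        for j in allowed:
            if states[j].emission not in used_syms:
                succ.append(int(j))
                used_syms.add(states[j].emission)
            if len(succ) == 3:
                break
        if rng.random() < 0.4 or not succ:
            succ.append(END)
        probs = rng.dirichlet(np.ones(len(succ))) * 0.8 + 0.2 / len(succ)
        for j, p in zip(succ, probs):
            trans[(i, int(j))] = float(p)
    head: list[int] = []
    head_syms: set[str] = set()
    for j in ids[: max(2, n_states // 2)]:
        if states[j].emission not in head_syms:
            head.append(j)
            head_syms.add(states[j].emission)
    n_starts = min(int(rng.integers(1, 3)), len(head))
    starts = list(rng.choice(head, size=n_starts, replace=False))
    probs = rng.dirichlet(np.ones(len(starts)))
    for j, p in zip(starts, probs):
        trans[(START, int(j))] = float(p)
    # every state must actually be visited often enough to survive the
    # derivation's reach pruning; DAG order makes the forward pass exact
    visit = {i: 0.0 for i in ids}
    for j, p in trans.items():
        if j[0] == START and j[1] != END:
            visit[j[1]] += p
    for i in ids:
        for j, p in ((jj, pp) for (ii, jj), pp in trans.items() if ii == i and jj != END):
            visit[j] += visit[i] * p
    if min(visit.values()) < 0.05:
        return None
    try:
        return StateModel(states, trans, alphabet)
    except ModelError:
        return None


def bengalese_like_pomma(rng_seed: int | None = None) -> StateModel:
    """Seven-syllable POMMA shaped like a Bengalese finch song syntax.

    Contains a peaked single-adaptive repeat state (C), an adaptive
    serial pair (A), a near-deterministic double-repeat serial pair (B),
    a geometric (non-adaptive) repeat state (G) and a second B state with
    a different continuation — a many-to-one mapping at the sequence
    level.  The ``rng_seed`` argument is accepted for interface symmetry;
    the fixture is fixed."""
    E, C, D, F, B1a, B1b, G, B2, A1, A2 = range(2, 12)
    mk = State
    states = {
        START: mk(START, None),
        END: mk(END, None),
        E: mk(E, "E"),
        C: mk(C, "C", self_p=0.9, alpha=0.5),
        D: mk(D, "D", self_p=0.8, alpha=0.6),
        F: mk(F, "F"),
        B1a: mk(B1a, "B"),
        B1b: mk(B1b, "B"),
        G: mk(G, "G", self_p=0.35, alpha=1.0),
        B2: mk(B2, "B"),
        A1: mk(A1, "A", self_p=0.85, alpha=0.55),
        A2: mk(A2, "A"),
    }
    trans = {
        (START, E): 1.0,
        (E, C): 0.6,
        (E, D): 0.4,
        (C, C): 0.9,
        (C, D): 0.07,
        (C, F): 0.03,
        (D, D): 0.8,
        (D, F): 0.16,
        (D, G): 0.04,
        (F, B1a): 0.8,
        (F, G): 0.2,
        (B1a, B1b): 0.97,
        (B1a, G): 0.015,
        (B1a, A1): 0.015,
        (B1b, G): 0.5,
        (B1b, A1): 0.5,
        (G, G): 0.35,
        (G, B2): 0.325,
        (G, A1): 0.325,
        (B2, A1): 1.0,
        (A1, A1): 0.85,
        (A1, A2): 0.1,
        (A1, END): 0.05,
        (A2, END): 1.0,
    }
    return StateModel(states, trans, Alphabet(tuple("ABCDEFG")))
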