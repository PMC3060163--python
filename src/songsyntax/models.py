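"""Unified state-transition model for syllable sequences.

One class covers the whole model family:

* Markov model — one state per syllable, fixed transition probabilities.
* Markov model with adaptation — a state's self-transition probability
  decays multiplicatively (factor ``alpha`` per consecutive visit), with
  the other outgoing probabilities rescaled to keep the total at 1; the
  probabilities recover when the state is left.
* POMM — several states may share one emission symbol; in the
  intermediate form produced by state merging, a state can carry an
  empirical repeat-number pmf instead of a self-transition.
* POMMA — POMM whose repeat states use adaptive self-transitions.

States are integers; ``START`` (0) and ``END`` (1) are structural and emit
nothing.  Transition probabilities live in ``StateModel.trans``; a state's
``self_p`` mirrors ``trans[(i, i)]``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Alphabet, Corpus, to_non_repeat

START = 0
END = 1

_SCHEMA = "songsyntax-statemodel"
_SCHEMA_VERSION = 1
PROB_TOL = 1e-9


class ModelError(ValueError):
    """Raised for structurally invalid models."""


@dataclass
class State:
    id: int
    emission: str | None  # None only for START/END
    self_p: float = 0.0
    alpha: float = 1.0
    repeat_pmf: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.self_p < 1.0):
            raise ModelError(f"state {self.id}: self_p must be in [0, 1)")
        if not (0.0 < self.alpha <= 1.0):
            raise ModelError(f"state {self.id}: alpha must be in (0, 1]")
        if self.repeat_pmf is not None and self.self_p != 0.0:
            raise ModelError(f"state {self.id}: repeat_pmf requires self_p = 0")

    @property
    def adaptive(self) -> bool:
        return self.self_p > 0 and self.alpha < 1.0


@dataclass
class StateModel:
    states: dict[int, State]
    trans: dict[tuple[int, int], float]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if START not in self.states or END not in self.states:
            raise ModelError("model must contain start and end states")
        for (i, j), p in self.trans.items():
            if p < 0:
                raise ModelError(f"negative transition probability {i}->{j}")
            if j == START:
                raise ModelError("transition into start state")
            if i == END:
                raise ModelError("transition out of end state")
        for i, st in self.states.items():
            if i == END:
                continue
            out = sum(p for (a, b), p in self.trans.items() if a == i)
            if abs(out - 1.0) > 1e-6:
                raise ModelError(f"outgoing probabilities of state {i} sum to {out}")
            if abs(st.self_p - self.trans.get((i, i), 0.0)) > PROB_TOL:
                raise ModelError(f"state {i}: self_p inconsistent with trans")
            if st.emission is not None and st.emission not in self.alphabet:
                raise ModelError(f"state {i}: emission {st.emission!r} not in alphabet")
        # end must be reachable from every state
        succ: dict[int, set[int]] = {}
        for (i, j), p in self.trans.items():
            if p > 0:
                succ.setdefault(i, set()).add(j)
        for i in self.states:
            if i == END:
                continue
            seen, stack = {i}, [i]
            while stack:
                u = stack.pop()
                for v in succ.get(u, ()):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if END not in seen:
                raise ModelError(f"end state unreachable from state {i}")

    def emitting_states(self) -> list[int]:
        return [i for i in self.states if i not in (START, END)]

    def successors(self, i: int) -> dict[int, float]:
        return {j: p for (a, j), p in self.trans.items() if a == i and p > 0}

    def states_for_symbol(self, sym: str) -> list[int]:
        return [i for i in self.emitting_states() if self.states[i].emission == sym]


# ---------------------------------------------------------------------------
# Markov fitting
# ---------------------------------------------------------------------------


def fit_markov(corpus: Corpus, prune: float = 0.01) -> StateModel:
    """One state per syllable; p_ij = frequency of the pair ij over the
    total frequency of syllable i (start -> first and last -> end included).
    Transitions with probability below ``prune`` are removed and the rest
    renormalized."""
    if not corpus.sequences:
        raise ModelError("empty corpus")
    ids = {sym: k + 2 for k, sym in enumerate(corpus.alphabet)}
    counts: dict[tuple[int, int], int] = {}
    for seq in corpus.sequences:
        prev = START
        for tok in seq:
            key = (prev, ids[tok])
            counts[key] = counts.get(key, 0) + 1
            prev = ids[tok]
        counts[(prev, END)] = counts.get((prev, END), 0) + 1

    totals: dict[int, int] = {}
    for (i, _), c in counts.items():
        totals[i] = totals.get(i, 0) + c
    trans = {(i, j): c / totals[i] for (i, j), c in counts.items()}
    trans = _prune_and_renormalize(trans, prune)

    states = {START: State(START, None), END: State(END, None)}
    for sym, i in ids.items():
        states[i] = State(i, sym, self_p=trans.get((i, i), 0.0))
    return StateModel(states, trans, corpus.alphabet)


def _prune_and_renormalize(
    trans: dict[tuple[int, int], float], floor: float
) -> dict[tuple[int, int], float]:
    kept = {k: p for k, p in trans.items() if p >= floor}
    out_sums: dict[int, float] = {}
    for (i, _), p in kept.items():
        out_sums[i] = out_sums.get(i, 0.0) + p
    for i in {k[0] for k in trans}:
        if i not in out_sums:
            raise ModelError(f"pruning removed every outgoing transition of state {i}")
    return {(i, j): p / out_sums[i] for (i, j), p in kept.items()}


def fit_markov_adaptation(
    corpus: Corpus, prune: float = 0.01, alpha_tol: float = 0.05, rng_seed: int = 0
) -> StateModel:
    """Markov fit plus adaptive self-transitions.

    For each state with a self-transition, (p, alpha) of the single-state
    adaptive repeat family are fit to the observed repeat-number pmf of the
    state's syllable by nonlinear least squares.  Fits returning alpha
    within ``alpha_tol`` of 1 leave the state non-adaptive."""
    from .distributions import repeat_distributions
    from . import repeat_models

    model = fit_markov(corpus, prune)
    repeats = repeat_distributions(corpus)
    states = dict(model.states)
    trans = dict(model.trans)
    for i in model.emitting_states():
        st = states[i]
        p_old = trans.get((i, i), 0.0)
        if p_old == 0.0 or st.emission not in repeats:
            continue
        try:
            fitres = repeat_models.fit("single", repeats[st.emission], rng_seed=rng_seed)
        except repeat_models.FitError:
            warnings.warn(f"adaptation fit failed for state {i}; left non-adaptive")
            continue
        p_new, alpha = fitres.model.params
        if alpha >= 1.0 - alpha_tol:
            continue
        scale = (1.0 - p_new) / (1.0 - p_old)
        for (a, b) in list(trans):
            if a == i:
                trans[(a, b)] = p_new if b == i else trans[(a, b)] * scale
        states[i] = State(i, st.emission, self_p=p_new, alpha=alpha)
    return StateModel(states, trans, model.alphabet)


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def _sample_pmf(pmf_keys, pmf_cum, u: float):
    idx = int(np.searchsorted(pmf_cum, u, side="right"))
    return pmf_keys[min(idx, len(pmf_keys) - 1)]


def generate(
    model: StateModel,
    n: int,
    rng_seed: int | None = None,
    max_len: int = 1000,
    strict: bool = False,
) -> Corpus:
    """Sample ``n`` sequences from the model.

    On the k-th consecutive visit to an adaptive state the self-transition
    probability is p * alpha**(k-1); conditional on leaving, the successor
    is drawn from the base non-self distribution (this is exactly the
    "rescale the others by (1 - p alpha**(k-1)) / (1 - p)" rule).  States
    with a repeat pmf emit their symbol r ~ pmf times and then move on.
    Sequences are truncated at ``max_len`` with a warning."""
    rng = np.random.default_rng(rng_seed)

    # precompute per-state successor tables
    succ: dict[int, tuple[list[int], np.ndarray]] = {}
    nonself: dict[int, tuple[list[int], np.ndarray]] = {}
    repeat_tab: dict[int, tuple[list[int], np.ndarray]] = {}
    for i in model.states:
        if i == END:
            continue
        s = model.successors(i)
        keys = sorted(s)
        probs = np.array([s[j] for j in keys])
        succ[i] = (keys, np.cumsum(probs))
        ns = {j: p for j, p in s.items() if j != i}
        total = sum(ns.values())
        if ns:
            nk = sorted(ns)
            nonself[i] = (nk, np.cumsum([ns[j] / total for j in nk]))
        st = model.states[i]
        if st.repeat_pmf:
            rk = sorted(st.repeat_pmf)
            repeat_tab[i] = (rk, np.cumsum([st.repeat_pmf[r] for r in rk]))

    sequences: list[list[str]] = []
    truncated = 0
    for _ in range(n):
        seq: list[str] = []
        state = START
        k = 0  # consecutive emissions in the current state
        while True:
            if len(seq) >= max_len:
                truncated += 1
                break
            if state == START:
                keys, cum = succ[state]
                state, k = _sample_pmf(keys, cum, rng.random()), 0
                continue
            if state == END:
                break
            st = model.states[state]
            if state in repeat_tab:
                rk, rcum = repeat_tab[state]
                r = _sample_pmf(rk, rcum, rng.random())
                seq.extend([st.emission] * min(r, max_len - len(seq)))
                keys, cum = nonself[state]
                state, k = _sample_pmf(keys, cum, rng.random()), 0
                continue
            seq.append(st.emission)
            k += 1
            p_self = st.self_p * st.alpha ** (k - 1)
            if p_self > 0 and rng.random() < p_self:
                continue  # stay: another consecutive visit
            if state in nonself:
                keys, cum = nonself[state]
                state, k = _sample_pmf(keys, cum, rng.random()), 0
            else:  # self-loop only possible exit is decay to... cannot happen (p<1)
                raise ModelError(f"state {state} has no non-self successor")
        if seq:
            sequences.append(seq)
    if truncated:
        msg = f"{truncated}/{n} sequences truncated at max_len={max_len}"
        if strict and truncated > 0.01 * n:
            raise ModelError(msg)
        warnings.warn(msg)
    return Corpus(sequences, model.alphabet)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def decode(model: StateModel, sequence: list[str]) -> list[int]:
    """Maximum-probability state path for a sequence.

    For models whose states carry empirical repeat pmfs the path is over
    maximal runs (one state id per run); otherwise it is token-level, with
    adaptation factors included in the path probability."""
    has_repeat = any(st.repeat_pmf for st in model.states.values())
    if has_repeat:
        return _decode_runs(model, sequence)
    return _decode_tokens(model, sequence)


def _decode_runs(model: StateModel, sequence: list[str]) -> list[int]:
    runs = []
    for tok in sequence:
        if runs and runs[-1][0] == tok:
            runs[-1] = (tok, runs[-1][1] + 1)
        else:
            runs.append((tok, 1))
    # Viterbi over runs
    best: dict[int, tuple[float, list[int]]] = {START: (0.0, [])}
    for sym, cnt in runs:
        nxt: dict[int, tuple[float, list[int]]] = {}
        for j in model.states_for_symbol(sym):
            pmf = model.states[j].repeat_pmf or {1: 1.0}
            emit_lp = math.log(pmf.get(cnt, 0.0)) if pmf.get(cnt, 0.0) > 0 else None
            if emit_lp is None:
                continue
            for i, (lp, path) in best.items():
                tp = model.trans.get((i, j), 0.0)
                if tp <= 0:
                    continue
                cand = lp + math.log(tp) + emit_lp
                if j not in nxt or cand > nxt[j][0]:
                    nxt[j] = (cand, path + [j])
        if not nxt:
            raise ModelError(f"sequence has zero probability under the model: {sequence}")
        best = nxt
    final = [
        (lp + math.log(model.trans[(i, END)]), path)
        for i, (lp, path) in best.items()
        if model.trans.get((i, END), 0.0) > 0
    ]
    if not final:
        raise ModelError(f"sequence has zero probability under the model: {sequence}")
    return max(final)[1]


def _decode_tokens(model: StateModel, sequence: list[str]) -> list[int]:
    # DP keys: (state, k) with k = consecutive emissions in the state so far
    best: dict[tuple[int, int], tuple[float, list[int]]] = {(START, 0): (0.0, [])}
    for tok in sequence:
        nxt: dict[tuple[int, int], tuple[float, list[int]]] = {}
        for (i, k), (lp, path) in best.items():
            st_i = model.states[i]
            for j, tp in model.successors(i).items():
                if j == END or model.states[j].emission != tok:
                    continue
                if j == i:
                    p_step = st_i.self_p * st_i.alpha ** (k - 1)
                    key = (j, k + 1)
                else:
                    p_step = tp * _leave_factor(st_i, k) if i != START else tp
                    key = (j, 1)
                if p_step <= 0:
                    continue
                cand = lp + math.log(p_step)
                if key not in nxt or cand > nxt[key][0]:
                    nxt[key] = (cand, path + [j])
        if not nxt:
            raise ModelError(f"sequence has zero probability under the model: {sequence}")
        best = nxt
    final = []
    for (i, k), (lp, path) in best.items():
        tp = model.trans.get((i, END), 0.0)
        if tp > 0:
            final.append((lp + math.log(tp * _leave_factor(model.states[i], k)), path))
    if not final:
        raise ModelError(f"sequence has zero probability under the model: {sequence}")
    return max(final)[1]


def _leave_factor(st: State, k: int) -> float:
    """Rescaling of non-self probabilities after k consecutive emissions."""
    if st.self_p == 0 or k == 0:
        return 1.0
    return (1.0 - st.self_p * st.alpha ** (k - 1)) / (1.0 - st.self_p)


def sequence_logprob(model: StateModel, sequence: list[str]) -> float:
    """Total log probability of a sequence (sum over all state paths).

    Brute-force-free only for models without shared emissions; with shared
    emissions this sums over the (state, consecutive-count) DP lattice."""
    has_repeat = any(st.repeat_pmf for st in model.states.values())
    if has_repeat:
        raise ModelError("sequence_logprob not defined for repeat-pmf models")
    # forward over (state, k)
    fwd: dict[tuple[int, int], float] = {(START, 0): 1.0}
    for tok in sequence:
        nxt: dict[tuple[int, int], float] = {}
        for (i, k), p in fwd.items():
            st_i = model.states[i]
            for j, tp in model.successors(i).items():
                if j == END or model.states[j].emission != tok:
                    continue
                if j == i:
                    step = st_i.self_p * st_i.alpha ** (k - 1)
                    key = (j, k + 1)
                else:
                    step = tp * _leave_factor(st_i, k) if i != START else tp
                    key = (j, 1)
                if step > 0:
                    nxt[key] = nxt.get(key, 0.0) + p * step
        if not nxt:
            return -math.inf
        fwd = nxt
    total = sum(
        p * model.trans.get((i, END), 0.0) * _leave_factor(model.states[i], k)
        for (i, k), p in fwd.items()
    )
    return math.log(total) if total > 0 else -math.inf


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: StateModel, path: str | Path) -> None:
    doc = {
        "schema": _SCHEMA,
        "version": _SCHEMA_VERSION,
        "alphabet": list(model.alphabet.symbols),
        "states": [
            {
                "id": st.id,
                "emission": st.emission,
                "self_p": st.self_p,
                "alpha": st.alpha,
                "repeat_pmf": (
                    {str(k): v for k, v in st.repeat_pmf.items()} if st.repeat_pmf else None
                ),
            }
            for st in model.states.values()
        ],
        "trans": [[i, j, p] for (i, j), p in sorted(model.trans.items())],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> StateModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _SCHEMA or doc.get("version") != _SCHEMA_VERSION:
        raise ModelError(f"unsupported model schema in {path}")
    states = {
        s["id"]: State(
            s["id"],
            s["emission"],
            self_p=s["self_p"],
            alpha=s["alpha"],
            repeat_pmf=(
                {int(k): v for k, v in s["repeat_pmf"].items()} if s["repeat_pmf"] else None
            ),
        )
        for s in doc["states"]
    }
    trans = {(i, j): p for i, j, p in doc["trans"]}
    return StateModel(states, trans, Alphabet(tuple(doc["alphabet"])))


def to_dot(model: StateModel) -> str:
    """GraphViz DOT rendering: every state labeled with its emission."""
    lines = ["digraph songsyntax {", "  rankdir=LR;"]
    for i, st in model.states.items():
        if i == START:
            label, shape = "start", "oval"
        elif i == END:
            label, shape = "end", "doublecircle"
        else:
            label = f"{st.emission} [{i}]"
            if st.adaptive:
                label += f"\\n(p={st.self_p:.2f}, a={st.alpha:.2f})"
            shape = "circle"
        lines.append(f'  n{i} [label="{label}", shape={shape}];')
    for (i, j), p in sorted(model.trans.items()):
        lines.append(f'  n{i} -> n{j} [label="{p:.2f}"];')
    lines.append("}")
    return "\n".join(lines)
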