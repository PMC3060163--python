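"""Derivation of a POMM from sequences by tree construction and state merging.

The non-repeat (run-length-encoded) sequences are first laid out as a tree
of states in which every observed sequence maps to a unique root-to-end
path; each state records how often its syllable's runs had each repeat
count, and the empirical distribution of the (length <= 15) symbol
sequences that followed it.  Same-symbol states whose suffix distributions
are similar (centered cosine above a threshold) are then merged until no
merger is possible, rare transitions and rarely-reached states are pruned,
and a final greedy refinement tests deletions and same-symbol mergers
against the d-value benchmarks of the observed corpus.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass


from .corpus import Alphabet, Corpus, NonRepeatCorpus, to_non_repeat
from .distributions import (
    DistributionSet,
    benchmark as _benchmark,
    compare,
    default_max_step,
    distribution_set,
)
from .models import END, START, ModelError, State, StateModel, generate

SUFFIX_MAX_LEN = 15


@dataclass
class PommConfig:
    merge_threshold: float = 0.95
    trans_floor: float = 0.01
    reach_floor: float = 0.005
    n_generate: int = 10_000
    benchmark_splits: int = 500
    benchmark_quantile: float = 0.95
    refine: bool = True
    rng_seed: int = 0


@dataclass
class CountModel:
    """Count-based intermediate POMM used throughout the derivation.

    Transition, repeat and suffix counts are kept (not probabilities) so
    that merging two states is exact pooling; probabilities are derived on
    conversion to a StateModel."""

    symbols: dict[int, str]  # emitting state id -> syllable
    trans_counts: dict[tuple[int, int], float]
    repeat_counts: dict[int, Counter]
    suffix_counts: dict[int, Counter]
    alphabet: Alphabet
    n_sequences: int

    def out_counts(self, i: int) -> float:
        return sum(c for (a, _), c in self.trans_counts.items() if a == i)

    def in_counts(self, i: int) -> float:
        return sum(c for (_, b), c in self.trans_counts.items() if b == i)

    def emitting_states(self) -> list[int]:
        return sorted(self.symbols)

    def to_state_model(self) -> StateModel:
        trans: dict[tuple[int, int], float] = {}
        outs: dict[int, float] = {}
        for (i, _), c in self.trans_counts.items():
            outs[i] = outs.get(i, 0.0) + c
        for (i, j), c in self.trans_counts.items():
            trans[(i, j)] = c / outs[i]
        states = {START: State(START, None), END: State(END, None)}
        for i, sym in self.symbols.items():
            rc = self.repeat_counts.get(i)
            total = sum(rc.values()) if rc else 0
            pmf = {n: c / total for n, c in sorted(rc.items())} if total else {1: 1.0}
            states[i] = State(i, sym, repeat_pmf=pmf)
        return StateModel(states, trans, self.alphabet)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def build_tree(corpus: NonRepeatCorpus) -> CountModel:
    """Translate non-repeat sequences into a tree-structured POMM.

    A new child state is created only when the current state has no child
    carrying the required symbol, so replaying any observed sequence
    visits exactly one path.  Repeat counts and (truncated) suffixes are
    accumulated per state."""
    if not corpus.sequences:
        raise ModelError("empty corpus")
    symbols: dict[int, str] = {}
    children: dict[tuple[int, str], int] = {}
    trans_counts: dict[tuple[int, int], float] = {}
    repeat_counts: dict[int, Counter] = {}
    suffix_counts: dict[int, Counter] = {}
    next_id = 2
    for seq in corpus.sequences:
        cur = START
        syms = [sym for sym, _ in seq]
        for idx, (sym, cnt) in enumerate(seq):
            child = children.get((cur, sym))
            if child is None:
                child = next_id
                next_id += 1
                children[(cur, sym)] = child
                symbols[child] = sym
                repeat_counts[child] = Counter()
                suffix_counts[child] = Counter()
            trans_counts[(cur, child)] = trans_counts.get((cur, child), 0) + 1
            repeat_counts[child][cnt] += 1
            suffix = tuple(syms[idx + 1 : idx + 1 + SUFFIX_MAX_LEN])
            suffix_counts[child][suffix] += 1
            cur = child
        trans_counts[(cur, END)] = trans_counts.get((cur, END), 0) + 1
    return CountModel(
        symbols, trans_counts, repeat_counts, suffix_counts, corpus.alphabet, len(corpus.sequences)
    )


def suffix_distribution(model: CountModel, state: int, max_len: int = SUFFIX_MAX_LEN) -> dict:
    """Empirical pmf over the (truncated) symbol sequences following a state."""
    if state not in model.suffix_counts:
        raise ModelError(f"state {state} not in model")
    counter = model.suffix_counts[state]
    if max_len < SUFFIX_MAX_LEN:
        counter = Counter()
        for suf, c in model.suffix_counts[state].items():
            counter[suf[:max_len]] += c
    total = sum(counter.values())
    return {suf: c / total for suf, c in counter.items()}


# ---------------------------------------------------------------------------
# State merging
# ---------------------------------------------------------------------------


def _suffix_similarity(c1: Counter, c2: Counter) -> float:
    """Cosine of two suffix pmfs on the union of their supports.

    The plain (uncentered) cosine is used here: suffix supports can be as
    small as two strings, where a mean-centered cosine degenerates to
    exactly +/-1 with the sign set by sampling noise, making equivalent
    states unmergeable.  The uncentered cosine of two probability vectors
    is well conditioned on any support size (1 iff the pmfs coincide).
    Sparse evaluation: only the common support contributes to the dot
    product."""
    t1 = sum(c1.values())
    t2 = sum(c2.values())
    common = set(c1) & set(c2)
    if len(c1) == len(c2) == len(common) == 1:
        return 1.0
    dot = sum((c1[k] / t1) * (c2[k] / t2) for k in common)
    sq1 = sum((v / t1) ** 2 for v in c1.values())
    sq2 = sum((v / t2) ** 2 for v in c2.values())
    return dot / math.sqrt(sq1 * sq2)


def _merge_pair(model: CountModel, keep: int, gone: int) -> None:
    """Pool ``gone`` into ``keep`` in place (counts are conserved)."""
    new_trans: dict[tuple[int, int], float] = {}
    for (i, j), c in model.trans_counts.items():
        a = keep if i == gone else i
        b = keep if j == gone else j
        new_trans[(a, b)] = new_trans.get((a, b), 0) + c
    model.trans_counts = new_trans
    model.repeat_counts[keep] += model.repeat_counts.pop(gone)
    model.suffix_counts[keep] += model.suffix_counts.pop(gone)
    del model.symbols[gone]


def merge_states(model: CountModel, similarity_threshold: float = 0.95) -> CountModel:
    """Iteratively merge same-symbol states with similar suffix pmfs.

    The most similar pair above the threshold is merged first (ties by
    lowest state ids), counts are pooled, and similarities involving the
    merged state are re-evaluated until no pair qualifies."""
    model = CountModel(
        dict(model.symbols),
        dict(model.trans_counts),
        {k: Counter(v) for k, v in model.repeat_counts.items()},
        {k: Counter(v) for k, v in model.suffix_counts.items()},
        model.alphabet,
        model.n_sequences,
    )
    by_symbol: dict[str, list[int]] = {}
    for i, sym in model.symbols.items():
        by_symbol.setdefault(sym, []).append(i)

    sims: dict[tuple[int, int], float] = {}
    for ids in by_symbol.values():
        ids.sort()
        for a_idx in range(len(ids)):
            for b_idx in range(a_idx + 1, len(ids)):
                a, b = ids[a_idx], ids[b_idx]
                sims[(a, b)] = _suffix_similarity(
                    model.suffix_counts[a], model.suffix_counts[b]
                )
    while sims:
        (a, b), s = max(sims.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
        if s < similarity_threshold:
            break
        _merge_pair(model, a, b)
        sym = model.symbols[a]
        by_symbol[sym].remove(b)
        sims = {k: v for k, v in sims.items() if a not in k and b not in k}
        for other in by_symbol[sym]:
            if other == a:
                continue
            key = (min(a, other), max(a, other))
            sims[key] = _suffix_similarity(
                model.suffix_counts[a], model.suffix_counts[other]
            )
    return model


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune(
    model: CountModel,
    trans_floor: float = 0.01,
    reach_floor: float = 0.005,
) -> CountModel:
    """Remove weak transitions and rarely-reached states.

    Transitions with probability below ``trans_floor`` are dropped; states
    reached fewer than ``reach_floor`` times per observed sequence (by
    their pooled incoming counts from the tree replay) are dropped with
    their transitions.  Dead-end states created by the removals are also
    dropped, and probabilities renormalize on conversion."""
    trans = dict(model.trans_counts)
    outs: dict[int, float] = {}
    for (i, _), c in trans.items():
        outs[i] = outs.get(i, 0.0) + c
    trans = {
        (i, j): c for (i, j), c in trans.items() if c / outs[i] >= trans_floor
    }
    keep = {
        i
        for i in model.symbols
        if sum(c for (_, b), c in trans.items() if b == i) / model.n_sequences
        >= reach_floor
    }
    while True:
        trans2 = {
            (i, j): c
            for (i, j), c in trans.items()
            if (i in keep or i == START) and (j in keep or j == END)
        }
        # states (or start) left without an outgoing transition are dead ends
        have_out = {i for (i, _) in trans2}
        dead = {i for i in keep if i not in have_out}
        if START not in have_out:
            raise ModelError("pruning isolated the start state")
        if not dead:
            trans = trans2
            break
        keep -= dead
    pruned = CountModel(
        {i: s for i, s in model.symbols.items() if i in keep},
        trans,
        {i: c for i, c in model.repeat_counts.items() if i in keep},
        {i: c for i, c in model.suffix_counts.items() if i in keep},
        model.alphabet,
        model.n_sequences,
    )
    pruned.to_state_model()  # raises if end became unreachable
    return pruned


# ---------------------------------------------------------------------------
# Refinement against benchmarks
# ---------------------------------------------------------------------------


def _evaluate(
    candidate: CountModel,
    observed_ds: DistributionSet,
    n_generate: int,
    seed: int,
) -> dict[str, float] | None:
    try:
        sm = candidate.to_state_model()
    except ModelError:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gen = generate(sm, n_generate, rng_seed=seed)
        gen_ds = distribution_set(gen, T=observed_ds.step.T)
        return compare(observed_ds, gen_ds).d_values


def _accepts(
    d: dict[str, float], benchmarks: dict[str, float], incumbent: dict[str, float]
) -> bool:
    return all(
        v <= benchmarks.get(k, math.inf) or v <= incumbent.get(k, math.inf)
        for k, v in d.items()
    )


def _delete_state(model: CountModel, state: int) -> CountModel:
    trans = {
        (i, j): c for (i, j), c in model.trans_counts.items() if state not in (i, j)
    }
    keep = set(model.symbols) - {state}
    while True:
        have_out = {i for (i, _) in trans}
        dead = {i for i in keep if i not in have_out}
        if not dead:
            break
        keep -= dead
        trans = {
            (i, j): c
            for (i, j), c in trans.items()
            if (i in keep or i == START) and (j in keep or j == END)
        }
    return CountModel(
        {i: s for i, s in model.symbols.items() if i in keep},
        trans,
        {i: c for i, c in model.repeat_counts.items() if i in keep},
        {i: c for i, c in model.suffix_counts.items() if i in keep},
        model.alphabet,
        model.n_sequences,
    )


def refine(
    model: CountModel,
    observed: Corpus,
    benchmarks: dict[str, float],
    n_generate: int = 10_000,
    rng_seed: int = 0,
    log: list | None = None,
) -> CountModel:
    """Greedy deletions and same-symbol mergers guided by d-values.

    Each candidate model generates ``n_generate`` sequences (with a fixed
    per-candidate seed) and is accepted iff every d-value is at or below
    its benchmark or at or below the incumbent's corresponding d-value.
    Passes repeat until no candidate is accepted."""
    observed_ds = distribution_set(observed)
    incumbent_d = _evaluate(model, observed_ds, n_generate, rng_seed)
    if incumbent_d is None:
        raise ModelError("refine: initial model is invalid")
    counter = 0
    improved = True
    while improved:
        improved = False
        # deletions first, then same-symbol mergers
        candidates: list[tuple[str, tuple]] = [
            ("delete", (i,)) for i in model.emitting_states()
        ]
        by_symbol: dict[str, list[int]] = {}
        for i, sym in model.symbols.items():
            by_symbol.setdefault(sym, []).append(i)
        for ids in by_symbol.values():
            ids.sort()
            candidates += [
                ("merge", (a, b))
                for ai, a in enumerate(ids)
                for b in ids[ai + 1 :]
            ]
        for kind, args in candidates:
            counter += 1
            # an earlier acceptance in this pass may have removed the state
            if any(s not in model.symbols for s in args):
                continue
            if kind == "delete":
                cand = _delete_state(model, args[0])
                if not cand.symbols:
                    continue
            else:
                cand = CountModel(
                    dict(model.symbols),
                    dict(model.trans_counts),
                    {k: Counter(v) for k, v in model.repeat_counts.items()},
                    {k: Counter(v) for k, v in model.suffix_counts.items()},
                    model.alphabet,
                    model.n_sequences,
                )
                _merge_pair(cand, *args)
            d = _evaluate(cand, observed_ds, n_generate, rng_seed + 1000 + counter)
            if d is None:
                continue
            if _accepts(d, benchmarks, incumbent_d):
                model = cand
                incumbent_d = d
                improved = True
                if log is not None:
                    log.append({"event": kind, "states": list(args), "d": d})
    return model


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def derive_pomm(
    corpus: Corpus,
    config: PommConfig | None = None,
    benchmarks: dict[str, float] | None = None,
    log: list | None = None,
) -> StateModel:
    """Tree construction, merging, pruning and refinement, end to end.

    Returns a POMM whose states carry the pooled empirical repeat-number
    pmfs of their syllables.  ``benchmarks`` may be passed to avoid
    recomputing the split-half noise floor."""
    cfg = config or PommConfig()
    tree = build_tree(to_non_repeat(corpus))
    if log is not None:
        log.append({"event": "tree", "states": len(tree.symbols)})
    merged = merge_states(tree, cfg.merge_threshold)
    if log is not None:
        log.append({"event": "merged", "states": len(merged.symbols)})
    pruned = prune(merged, cfg.trans_floor, cfg.reach_floor)
    if log is not None:
        log.append({"event": "pruned", "states": len(pruned.symbols)})
    if cfg.refine:
        if benchmarks is None:
            benchmarks = _benchmark(
                corpus,
                n_splits=cfg.benchmark_splits,
                quantile=cfg.benchmark_quantile,
                rng_seed=cfg.rng_seed,
            )
        pruned = refine(
            pruned, corpus, benchmarks, cfg.n_generate, cfg.rng_seed, log=log
        )
        if log is not None:
            log.append({"event": "refined", "states": len(pruned.symbols)})
    return pruned.to_state_model()
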