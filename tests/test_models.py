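"""State-transition models: Markov fitting, adaptive generation, decoding,
serialization."""

import itertools
import json
import math

import numpy as np
import pytest

from songsyntax.corpus import Alphabet, Corpus
from songsyntax.distributions import d_value, ngram_distributions, repeat_distributions
from songsyntax.models import (
    END,
    START,
    ModelError,
    State,
    StateModel,
    decode,
    fit_markov,
    fit_markov_adaptation,
    generate,
    load_model,
    save_model,
    to_dot,
)
from songsyntax.repeat_models import pmf_single

from conftest import make_corpus


def chain_model(*symbols: str) -> StateModel:
    """Deterministic s -> symbols... -> e chain."""
    states = {START: State(START, None), END: State(END, None)}
    trans = {}
    prev = START
    for k, sym in enumerate(symbols, start=2):
        states[k] = State(k, sym)
        trans[(prev, k)] = 1.0
        prev = k
    trans[(prev, END)] = 1.0
    return StateModel(states, trans, Alphabet(tuple(dict.fromkeys(symbols))))


def single_state_model(p: float, alpha: float = 1.0, repeat_pmf=None) -> StateModel:
    st = State(2, "A", self_p=p, alpha=alpha, repeat_pmf=repeat_pmf)
    states = {START: State(START, None), END: State(END, None), 2: st}
    trans = {(START, 2): 1.0, (2, END): 1.0 - p}
    if p > 0:
        trans[(2, 2)] = p
    return StateModel(states, trans, Alphabet(("A",)))


class TestFitMarkov:
    def test_deterministic_corpus(self):
        m = fit_markov(make_corpus("AB", "AB"))
        a, b = m.states_for_symbol("A")[0], m.states_for_symbol("B")[0]
        assert m.trans[(START, a)] == 1.0
        assert m.trans[(a, b)] == 1.0
        assert m.trans[(b, END)] == 1.0

    def test_hand_counted_probabilities(self):
        # "AA","AB": out of A -> A once, B once, e once (the final A of AA)
        m = fit_markov(make_corpus("AA", "AB"))
        a = m.states_for_symbol("A")[0]
        b = m.states_for_symbol("B")[0]
        assert m.trans[(a, a)] == pytest.approx(1 / 3)
        assert m.trans[(a, b)] == pytest.approx(1 / 3)
        assert m.trans[(a, END)] == pytest.approx(1 / 3)

    def test_rare_transition_pruned(self):
        seqs = ["AB"] * 999 + ["AC"]
        m = fit_markov(make_corpus(*seqs), prune=0.01)
        a = m.states_for_symbol("A")[0]
        c = m.states_for_symbol("C")[0]
        assert (a, c) not in m.trans
        b = m.states_for_symbol("B")[0]
        assert m.trans[(a, b)] == pytest.approx(1.0)  # renormalized

    def test_generated_bigrams_match_corpus(self):
        # the Markov model reproduces 2-grams by construction (sampling error)
        corpus = make_corpus(*(["AAB", "ABB", "AB", "BA"] * 50))
        m = fit_markov(corpus, prune=0.0)
        gen = generate(m, 10_000, rng_seed=0)
        d = d_value(
            ngram_distributions(corpus, (2,))[2].pmf,
            ngram_distributions(gen, (2,))[2].pmf,
        )
        assert d < 0.05


class TestGenerate:
    def test_deterministic_chain(self):
        c = generate(chain_model("A", "B"), 50, rng_seed=1)
        assert all(seq == ["A", "B"] for seq in c.sequences)

    def test_seeded_determinism(self):
        m = fit_markov(make_corpus("AAB", "AB", "ABB"))
        c1 = generate(m, 200, rng_seed=42)
        c2 = generate(m, 200, rng_seed=42)
        assert c1.sequences == c2.sequences

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_run_lengths_match_closed_form(self, alpha):
        # alpha=1 -> geometric; alpha<1 -> adaptive closed form
        n = 100_000
        c = generate(single_state_model(0.5, alpha), n, rng_seed=3)
        pmf = repeat_distributions(c)["A"].pmf
        expected = pmf_single(0.5, alpha).pmf
        for k, p in expected.items():
            if p < 1e-6:
                continue
            se = math.sqrt(p * (1 - p) / n)
            assert abs(pmf.get(k, 0.0) - p) < 3 * se + 1e-9

    def test_repeat_pmf_states_emit_sampled_runs(self):
        m = single_state_model(0.0, repeat_pmf={2: 0.25, 3: 0.75})
        c = generate(m, 4000, rng_seed=4)
        pmf = repeat_distributions(c)["A"].pmf
        assert set(pmf) == {2, 3}
        assert pmf[3] == pytest.approx(0.75, abs=0.03)

    def test_truncation_warns(self):
        m = single_state_model(0.9)
        with pytest.warns(UserWarning, match="truncated"):
            generate(m, 300, rng_seed=5, max_len=2)


class TestFitMarkovAdaptation:
    def test_geometric_runs_stay_non_adaptive(self):
        rng = np.random.default_rng(8)
        seqs = [["A"] * int(k) + ["B"] for k in rng.geometric(0.45, size=3000)]
        m = fit_markov_adaptation(Corpus(seqs, Alphabet(("A", "B"))), rng_seed=0)
        a = m.states_for_symbol("A")[0]
        assert not m.states[a].adaptive

    def test_parameter_recovery(self):
        m_true = single_state_model(0.9, 0.6)
        c = generate(m_true, 5000, rng_seed=9)
        m = fit_markov_adaptation(c, rng_seed=0)
        st = m.states[m.states_for_symbol("A")[0]]
        assert st.self_p == pytest.approx(0.9, abs=0.05)
        assert st.alpha == pytest.approx(0.6, abs=0.05)

    def test_peaked_repeat_distribution_reproduced(self):
        # adaptation produces an interior mode that plain Markov cannot
        c = generate(single_state_model(0.9, 0.5), 5000, rng_seed=10)
        m = fit_markov_adaptation(c, rng_seed=0)
        gen = generate(m, 20_000, rng_seed=11)
        pmf = repeat_distributions(gen)["A"].pmf
        mode = max(pmf, key=pmf.get)
        assert mode > 1


class TestAdaptationNormalization:
    def test_scaled_probabilities_sum_to_one(self):
        # self p*a^(k-1) plus others scaled by (1-p a^(k-1))/(1-p) is 1
        p, a = 0.7, 0.6
        others = [0.2, 0.1]
        for k in range(1, 10):
            pk = p * a ** (k - 1)
            f = (1 - pk) / (1 - p)
            assert pk + sum(o * f for o in others) == pytest.approx(1.0)


class TestDecode:
    def test_forced_path(self):
        m = chain_model("A", "B")
        assert decode(m, ["A", "B"]) == [2, 3]

    def test_successor_determines_state(self):
        # two states for "A" with disjoint successors
        states = {
            START: State(START, None),
            END: State(END, None),
            2: State(2, "A"),
            3: State(3, "A"),
            4: State(4, "B"),
            5: State(5, "C"),
        }
        trans = {
            (START, 2): 0.5,
            (START, 3): 0.5,
            (2, 4): 1.0,
            (3, 5): 1.0,
            (4, END): 1.0,
            (5, END): 1.0,
        }
        m = StateModel(states, trans, Alphabet(("A", "B", "C")))
        assert decode(m, ["A", "B"]) == [2, 4]
        assert decode(m, ["A", "C"]) == [3, 5]

    def test_zero_probability_sequence_rejected(self):
        with pytest.raises(ModelError):
            decode(chain_model("A", "B"), ["B", "A"])

    def test_matches_brute_force_enumeration(self):
        # compare against explicit enumeration of all state paths
        states = {
            START: State(START, None),
            END: State(END, None),
            2: State(2, "A", self_p=0.4, alpha=0.7),
            3: State(3, "B"),
            4: State(4, "A"),
        }
        trans = {
            (START, 2): 0.7,
            (START, 4): 0.3,
            (2, 2): 0.4,
            (2, 3): 0.4,
            (2, END): 0.2,
            (3, 4): 0.6,
            (3, END): 0.4,
            (4, 3): 0.5,
            (4, END): 0.5,
        }
        m = StateModel(states, trans, Alphabet(("A", "B")))

        def leave(st, k):
            if st.self_p == 0:
                return 1.0
            return (1 - st.self_p * st.alpha ** (k - 1)) / (1 - st.self_p)

        def path_prob(path, seq):
            p = 1.0
            prev, k = START, 0
            for s, tok in zip(path, seq):
                if m.states[s].emission != tok:
                    return 0.0
                if s == prev:
                    p *= m.states[s].self_p * m.states[s].alpha ** (k - 1)
                    k += 1
                else:
                    tp = m.trans.get((prev, s), 0.0)
                    p *= tp if prev == START else tp * leave(m.states[prev], k)
                    k = 1
                prev = s
            tp = m.trans.get((prev, END), 0.0)
            return p * tp * leave(m.states[prev], k)

        emitting = [2, 3, 4]
        for seq in [list("AB"), list("AAB"), list("ABA"), list("AABA"), list("AABAB")]:
            probs = {
                path: path_prob(path, seq)
                for path in itertools.product(emitting, repeat=len(seq))
            }
            best_path = max(probs, key=probs.get)
            if probs[best_path] == 0:
                continue
            got = decode(m, seq)
            assert probs[tuple(got)] == pytest.approx(probs[best_path])


class TestSerialization:
    def test_round_trip(self, tmp_path):
        m = fit_markov(make_corpus("AAB", "AB", "ABB"))
        p = tmp_path / "m.json"
        save_model(m, p)
        back = load_model(p)
        assert back.trans == m.trans
        assert {i: s.emission for i, s in back.states.items()} == {
            i: s.emission for i, s in m.states.items()
        }

    def test_invalid_probabilities_rejected(self, tmp_path):
        m = fit_markov(make_corpus("AB"))
        p = tmp_path / "m.json"
        save_model(m, p)
        doc = json.loads(p.read_text())
        doc["trans"] = [[i, j, pr * 1.2] for i, j, pr in doc["trans"]]
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelError):
            load_model(p)

    def test_schema_mismatch_rejected(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text(json.dumps({"schema": "other", "version": 9}))
        with pytest.raises(ModelError):
            load_model(p)

    def test_dot_export_labels_states(self):
        m = fit_markov(make_corpus("AB", "AB"))
        dot = to_dot(m)
        assert "digraph" in dot
        for sym in ("A", "B"):
            assert sym in dot


class TestValidation:
    def test_end_must_be_reachable(self):
        states = {
            START: State(START, None),
            END: State(END, None),
            2: State(2, "A"),
            3: State(3, "B"),
        }
        # state 3 only loops back to 2 which only goes to 3: end unreachable
        trans = {(START, 2): 1.0, (2, 3): 1.0, (3, 2): 1.0}
        with pytest.raises(ModelError, match="unreachable"):
            StateModel(states, trans, Alphabet(("A", "B")))

    def test_rows_must_normalize(self):
        states = {START: State(START, None), END: State(END, None), 2: State(2, "A")}
        trans = {(START, 2): 1.0, (2, END): 0.8}
        with pytest.raises(ModelError, match="sum"):
            StateModel(states, trans, Alphabet(("A",)))
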