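"""Features, legality, transitions and retrieval-driven parsing."""

import numpy as np
import pytest

import ratparse as rp
from ratparse import parser as ps
from ratparse.treebank import Action

TOKENS = [("a", "DT"), ("boy", "NN"), ("dances", "VBZ")]


# ---------------------------------------------------------------------------
# feature extraction


def test_initial_state_features():
    state = ps.initial_state(TOKENS)
    feats = ps.extract_features(state)
    assert len(feats) == 19
    assert all(feats[k] == "none" for k in feats if k.startswith("s"))
    assert feats["q1_lemma"] == "a" and feats["q1_pos"] == "DT"
    assert feats["q2_lemma"] == "boy" and feats["q2_pos"] == "NN"
    assert feats["gaps_since_shift"] == "gaps0"
    assert feats["filler_present"] == "nofiller"


def test_features_after_shifts():
    state = ps.initial_state(TOKENS)
    state = ps.apply_action(state, Action(Action.SHIFT))
    state = ps.apply_action(state, Action(Action.SHIFT))
    feats = ps.extract_features(state)
    assert feats["s1_label"] == "NN" and feats["s2_label"] == "DT"
    assert feats["s1_head_lemma"] == "boy"
    assert feats["q1_lemma"] == "dance" and feats["q2_lemma"] == "none"


def test_empty_queue_features():
    state = ps.initial_state([("boy", "NN")])
    state = ps.apply_action(state, Action(Action.SHIFT))
    feats = ps.extract_features(state)
    assert feats["q1_lemma"] == "none" and feats["q2_pos"] == "none"


def test_feature_subset_is_configurable():
    state = ps.initial_state(TOKENS)
    feats = ps.extract_features(state, names=("q1_pos", "gaps_since_shift"))
    assert list(feats) == ["q1_pos", "gaps_since_shift"]
    with pytest.raises(ValueError, match="unknown feature"):
        ps.extract_features(state, names=("nope",))


def test_none_features_spread_no_activation():
    state = ps.initial_state(TOKENS)
    cues = ps.context_cues(ps.extract_features(state))
    assert "none" not in cues


# ---------------------------------------------------------------------------
# legality


def test_legality_constraints():
    s0 = ps.initial_state(TOKENS)
    assert ps.legal_actions(s0) == {Action.SHIFT}
    s1 = ps.apply_action(s0, Action(Action.SHIFT))
    assert ps.legal_actions(s1) == {Action.SHIFT, Action.REDUCE_UNARY}
    s2 = ps.apply_action(s1, Action(Action.SHIFT))
    s3 = ps.apply_action(s2, Action(Action.SHIFT))
    # queue empty, 3 trees on the stack
    assert ps.legal_actions(s3) == {Action.REDUCE_UNARY, Action.REDUCE_BINARY}


def test_gap_requires_filler_and_is_capped_at_two():
    state = ps.initial_state([("who", "WP"), ("dances", "VBZ")])
    state = ps.apply_action(state, Action(Action.SHIFT))  # registers the filler
    assert Action.POSTULATE_GAP in ps.legal_actions(state)
    g = Action(Action.POSTULATE_GAP, gap_info="NP")
    state = ps.apply_action(state, g)
    state = ps.apply_action(state, g)
    assert state.gaps_since_shift == 2
    with pytest.raises(ps.ParseError, match="two gaps"):
        ps.apply_action(state, g)
    # a shift resets the counter
    state = ps.apply_action(state, Action(Action.SHIFT))
    assert state.gaps_since_shift == 0


def test_gap_without_filler_is_illegal():
    state = ps.initial_state(TOKENS)
    with pytest.raises(ps.ParseError, match="no wh-filler"):
        ps.apply_action(state, Action(Action.POSTULATE_GAP, gap_info="NP"))


def test_illegal_actions_name_the_constraint():
    state = ps.initial_state(TOKENS)
    with pytest.raises(ps.ParseError, match="stack is empty"):
        ps.apply_action(state, Action(Action.REDUCE_UNARY, label="NP"))
    drained = ps.initial_state([("boy", "NN")])
    drained = ps.apply_action(drained, Action(Action.SHIFT))
    with pytest.raises(ps.ParseError, match="queue.*empty"):
        ps.apply_action(drained, Action(Action.SHIFT))


# ---------------------------------------------------------------------------
# transitions


def test_shift_and_reduce_build_headed_trees():
    state = ps.initial_state(TOKENS)
    state = ps.apply_action(state, Action(Action.SHIFT))
    assert state.stack[0].terminal == "a" and state.stack[0].label == "DT"
    assert [w for w, _, _ in state.queue] == ["boy", "dances"]
    state = ps.apply_action(state, Action(Action.SHIFT))
    state = ps.apply_action(state, Action(Action.REDUCE_BINARY, label="NP"))
    np_tree = state.stack[-1]
    assert np_tree.label == "NP" and np_tree.head == ("boy", "NN")


# ---------------------------------------------------------------------------
# decide_step and majority voting


def _step_memory(slot_actions):
    """Memory of chunks with given (action, action_label, extra-slots)."""
    mem = rp.DeclarativeMemory()
    for i, (kind, label, extra, n) in enumerate(slot_actions):
        slots = {"action": kind, "action_label": label, "id": f"c{i}", **extra}
        mem.add(rp.Chunk(slots, rp.PresentationSchedule(n=n, span=100.0)))
    return mem


def test_majority_action_wins():
    mem = _step_memory([
        ("reduce_binary", "NP", {}, 50),
        ("reduce_binary", "NP", {"x": "y"}, 40),
        ("shift", "none", {}, 100),
        ("reduce_unary", "VP", {}, 1),
    ])
    state = ps.initial_state(TOKENS)
    state = ps.apply_action(state, Action(Action.SHIFT))
    state = ps.apply_action(state, Action(Action.SHIFT))
    action, act = ps.decide_step(state, mem, rp.ActivationParams())
    assert action == Action(Action.REDUCE_BINARY, label="NP")
    assert np.isfinite(act)


def test_three_way_tie_goes_to_top_chunk():
    mem = _step_memory([
        ("shift", "none", {}, 100),          # highest base level
        ("reduce_binary", "NP", {}, 10),
        ("reduce_unary", "VP", {}, 1),
    ])
    state = ps.initial_state(TOKENS)
    state = ps.apply_action(state, Action(Action.SHIFT))
    state = ps.apply_action(state, Action(Action.SHIFT))
    action, _ = ps.decide_step(state, mem, rp.ActivationParams())
    assert action == Action(Action.SHIFT)


def test_single_chunk_memory_truncates_k():
    mem = _step_memory([("shift", "none", {}, 5)])
    state = ps.initial_state(TOKENS)
    action, _ = ps.decide_step(state, mem, rp.ActivationParams())
    assert action == Action(Action.SHIFT)


def test_candidates_restricted_to_legal_actions():
    # only a reduce chunk exists but the initial state allows only shift
    mem = _step_memory([("reduce_unary", "NP", {}, 5)])
    state = ps.initial_state(TOKENS)
    with pytest.raises(ps.ParseError, match="parse failure"):
        ps.decide_step(state, mem, rp.ActivationParams())


# ---------------------------------------------------------------------------
# full parses


def _fig1_style_memory():
    """~50 trees of the Fig.-1 shape with varied lexemes."""
    nouns = ["boy", "girl", "man", "dog", "cat", "friend", "horse"]
    verbs = ["dances", "runs", "sleeps", "barks", "falls", "races", "sees"]
    trees = [
        rp.prepare(rp.read_trees(f"(S (NP (DT a) (NN {n})) (VP (VBZ {v})))")[0])
        for n in nouns for v in verbs
    ]
    return trees[0], rp.collect_chunks(trees, prepared=True)


def test_parse_forced_by_matching_memory():
    """A memory containing only Fig.-1-style steps forces the exact tree."""
    tree, mem = _fig1_style_memory()
    result = ps.parse_sentence(TOKENS, mem, rp.ActivationParams())
    assert result.complete
    assert result.tree == tree
    assert len(result.word_activations) == 3


def test_parse_single_word(memory, default_params):
    result = ps.parse_sentence([("boy", "NN")], memory, default_params)
    assert len(result.word_activations) == 1


def test_parse_activation_length_equals_sentence_length(memory, default_params, grammar):
    for t in rp.read_trees(rp.toy_treebank(grammar, 10, seed=77)):
        toks = [(w, p) for w, _, p in rp.prepare(t).words()]
        res = ps.parse_sentence(toks, memory, default_params)
        assert len(res.word_activations) == len(toks)


def test_parse_deterministic(memory, default_params):
    toks = [("the", "DT"), ("dog", "NN"), ("sees", "VBZ"), ("the", "DT"), ("cat", "NN")]
    r1 = ps.parse_sentence(toks, memory, default_params)
    r2 = ps.parse_sentence(toks, memory, default_params)
    assert r1.actions == r2.actions
    assert r1.word_activations == r2.word_activations


def test_unknown_pos_raises_but_unknown_lemma_is_fine(memory, default_params):
    with pytest.raises(ps.ParseError, match="unknown POS"):
        ps.parse_sentence([("blorp", "XQZ")], memory, default_params)
    # an unseen word with a known tag parses: its lemma matches no cue
    res = ps.parse_sentence([("the", "DT"), ("zyzzyva", "NN"), ("dances", "VBZ")],
                            memory, default_params)
    assert len(res.word_activations) == 3


# ---------------------------------------------------------------------------
# guided mode


def test_guided_matches_free_parse_when_gold_agrees(default_params):
    tree, mem = _fig1_style_memory()
    free = ps.parse_sentence(TOKENS, mem, default_params)
    guided = ps.guided_parse(TOKENS, tree, mem, default_params)
    assert guided == pytest.approx(free.word_activations)


def test_guided_defined_even_without_matching_chunks(memory, default_params):
    """Retrieval scores are graded, so novel gold contexts still retrieve."""
    raw = rp.read_trees("(S (NP (DT the) (NN horse)) (VP (VBZ sees) (NP (DT a) (NN friend))))")[0]
    tree = rp.prepare(raw)
    toks = [(w, p) for w, _, p in tree.words()]
    acts = ps.guided_parse(toks, tree, memory, default_params)
    assert len(acts) == len(toks)
    assert all(np.isfinite(a) for a in acts)


def test_guided_rejects_mismatched_gold(memory, default_params):
    tree = rp.prepare(rp.read_trees("(S (NP (DT a) (NN boy)) (VP (VBZ dances)))")[0])
    with pytest.raises(ps.ParseError, match="do not match"):
        ps.guided_parse([("a", "DT"), ("girl", "NN"), ("dances", "VBZ")],
                        tree, memory, default_params)
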