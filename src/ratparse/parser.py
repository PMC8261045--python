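"""Transition-based constituency parsing driven by declarative-memory retrieval.

The parser's working memory is a stack of partial trees and a queue of
upcoming (word, POS) pairs.  At every step it extracts a small feature
context from the state, lets those features spread activation to the stored
parsing-step chunks, retrieves the top-k (default 3) among chunks whose
action is legal, and applies the majority action.  The activations of the
retrieved chunks, averaged per word, are the model's measure of processing
difficulty.

Legality constraints: no shift with an empty queue; no reduce with an empty
stack; no binary reduce with fewer than two trees; at most two postulated
gaps between shifts, and only when a wh-filler has been shifted earlier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .memory_core import (
    ActivationParams,
    DeclarativeMemory,
    NONE_ATOM,
)
from .treebank import (
    Action,
    GAP_ATOM,
    PhraseTree,
    head_for,
    lemmatize,
    oracle_actions,
)


class ParseError(ValueError):
    pass


#: POS tags whose shift registers a wh-filler available for gap resolution
WH_POS = frozenset({"WP", "WDT", "WP$", "WRB"})


@dataclass(frozen=True)
class Filler:
    """A shifted wh-element available as the antecedent of a gap."""

    lemma: str
    pos: str
    encoding_time: float


@dataclass(frozen=True)
class ParserState:
    """Immutable parser configuration.

    stack   partial trees, rightmost = top
    queue   upcoming (word, lemma, POS) triples
    gaps_since_shift  bounded at 2 by the legality constraints
    fillers shifted wh-elements, most recent last
    """

    stack: tuple = ()
    queue: tuple = ()
    gaps_since_shift: int = 0
    fillers: tuple = ()

    def __post_init__(self):
        if not 0 <= self.gaps_since_shift <= 2:
            raise ParseError("gaps_since_shift out of range")


def initial_state(tokens: Sequence) -> ParserState:
    """Initial state for a sentence of (word, lemma, POS) triples.

    Two-element (word, POS) pairs are accepted; lemmas are then filled in
    by the default lemma dictionary.
    """
    queue = []
    for tok in tokens:
        if len(tok) == 3:
            word, lemma, pos = tok
        else:
            word, pos = tok
            lemma = lemmatize(word)
        queue.append((word, lemma, pos))
    return ParserState(queue=tuple(queue))


# ---------------------------------------------------------------------------
# feature extraction

#: default 19-feature context: three stack positions (category, head lemma,
#: head POS), daughter categories of the top two stack trees, two queue
#: positions (lemma, POS), the gap counter and the filler flag.
DEFAULT_FEATURE_NAMES = (
    "s1_label", "s1_head_lemma", "s1_head_pos",
    "s2_label", "s2_head_lemma", "s2_head_pos",
    "s3_label", "s3_head_lemma", "s3_head_pos",
    "s1_left_label", "s1_right_label",
    "s2_left_label", "s2_right_label",
    "q1_lemma", "q1_pos", "q2_lemma", "q2_pos",
    "gaps_since_shift", "filler_present",
)


def _stack_tree(state: ParserState, depth: int) -> Optional[PhraseTree]:
    return state.stack[-depth] if len(state.stack) >= depth else None


def _tree_feats(tree: Optional[PhraseTree]):
    if tree is None:
        return NONE_ATOM, NONE_ATOM, NONE_ATOM
    head = tree.head or (NONE_ATOM, NONE_ATOM)
    return tree.label, head[0], head[1]


def _daughter_labels(tree: Optional[PhraseTree]):
    if tree is None or tree.is_leaf:
        return NONE_ATOM, NONE_ATOM
    if len(tree.children) == 1:
        return tree.children[0].label, NONE_ATOM
    return tree.children[0].label, tree.children[-1].label


def extract_features(state: ParserState, names: Sequence[str] = DEFAULT_FEATURE_NAMES) -> dict:
    """Deterministic feature context; absent positions carry the none atom."""
    s1, s2, s3 = (_stack_tree(state, i) for i in (1, 2, 3))
    q1 = state.queue[0] if len(state.queue) >= 1 else None
    q2 = state.queue[1] if len(state.queue) >= 2 else None
    full = {}
    full["s1_label"], full["s1_head_lemma"], full["s1_head_pos"] = _tree_feats(s1)
    full["s2_label"], full["s2_head_lemma"], full["s2_head_pos"] = _tree_feats(s2)
    full["s3_label"], full["s3_head_lemma"], full["s3_head_pos"] = _tree_feats(s3)
    full["s1_left_label"], full["s1_right_label"] = _daughter_labels(s1)
    full["s2_left_label"], full["s2_right_label"] = _daughter_labels(s2)
    full["q1_lemma"] = q1[1] if q1 else NONE_ATOM
    full["q1_pos"] = q1[2] if q1 else NONE_ATOM
    full["q2_lemma"] = q2[1] if q2 else NONE_ATOM
    full["q2_pos"] = q2[2] if q2 else NONE_ATOM
    full["gaps_since_shift"] = f"gaps{state.gaps_since_shift}"
    full["filler_present"] = "filler" if state.fillers else "nofiller"
    unknown = set(names) - set(full)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    return {k: full[k] for k in names}


def cue_atom(slot: str, value) -> str:
    """Render a feature as a slot-qualified cue atom.

    The cue is the *positional* property ("NP at stack top"), not the bare
    value: the same label in different positions is different evidence, and
    the fan of a cue counts the parsing steps sharing that property.
    """
    return f"{slot}={value}"


def context_cues(features: dict) -> frozenset:
    """Cue atoms that spread activation (none-valued features spread nothing)."""
    return frozenset(cue_atom(k, v) for k, v in features.items() if v != NONE_ATOM)


# ---------------------------------------------------------------------------
# transitions


def legal_actions(state: ParserState) -> frozenset:
    """The action kinds permitted in ``state``."""
    kinds = set()
    if state.queue:
        kinds.add(Action.SHIFT)
    if state.stack:
        kinds.add(Action.REDUCE_UNARY)
    if len(state.stack) >= 2:
        kinds.add(Action.REDUCE_BINARY)
    if state.gaps_since_shift < 2 and state.fillers:
        kinds.add(Action.POSTULATE_GAP)
    return frozenset(kinds)


def apply_action(state: ParserState, action: Action, now: float = 0.0) -> ParserState:
    """Apply a legal action; raises :class:`ParseError` naming the violated
    constraint otherwise."""
    if action.kind not in legal_actions(state):
        raise ParseError(_violation(state, action))
    if action.kind == Action.SHIFT:
        word, lemma, pos = state.queue[0]
        leaf = PhraseTree(pos, terminal=word, lemma=lemma, head=(lemma, pos))
        fillers = state.fillers
        if pos in WH_POS:
            fillers = fillers + (Filler(lemma, pos, now),)
        return ParserState(state.stack + (leaf,), state.queue[1:], 0, fillers)
    if action.kind == Action.REDUCE_UNARY:
        child = state.stack[-1]
        node = PhraseTree(action.label, (child,), head=child.head)
        return ParserState(
            state.stack[:-1] + (node,), state.queue, state.gaps_since_shift, state.fillers
        )
    if action.kind == Action.REDUCE_BINARY:
        left, right = state.stack[-2], state.stack[-1]
        node = PhraseTree(action.label, (left, right), head=head_for(action.label, (left, right)))
        return ParserState(
            state.stack[:-2] + (node,), state.queue, state.gaps_since_shift, state.fillers
        )
    # postulate_gap: push a gap element bound to the most recent filler
    gap = PhraseTree(action.gap_info, gap=True, head=(GAP_ATOM, action.gap_info))
    return ParserState(
        state.stack + (gap,), state.queue, state.gaps_since_shift + 1, state.fillers
    )


def _violation(state: ParserState, action: Action) -> str:
    if action.kind == Action.SHIFT:
        return "illegal shift: the queue of upcoming words is empty"
    if action.kind == Action.REDUCE_UNARY:
        return "illegal reduce: the stack is empty"
    if action.kind == Action.REDUCE_BINARY:
        return "illegal reduce binary: fewer than two trees on the stack"
    if state.gaps_since_shift >= 2:
        return "illegal postulate gap: two gaps already postulated since the last shift"
    return "illegal postulate gap: no wh-filler has been shifted"


def _check_pos_known(state: ParserState, memory: DeclarativeMemory) -> None:
    """Gold POS tags are assumed; a tag never seen in memory is an error
    (an unknown lemma, by contrast, simply matches no cue)."""
    for word, _, pos in state.queue:
        if memory.fan(cue_atom("q1_pos", pos)) == 0:
            raise ParseError(f"unknown POS tag {pos!r} on word {word!r}")


# ---------------------------------------------------------------------------
# retrieval-driven stepping


def _chunk_action(chunk) -> Action:
    kind = chunk.slots["action"]
    label = chunk.slots.get("action_label", "none")
    if kind in (Action.REDUCE_UNARY, Action.REDUCE_BINARY):
        return Action(kind, label=label)
    if kind == Action.POSTULATE_GAP:
        return Action(kind, gap_info=label)
    return Action(kind)


def retrieve_step(
    state: ParserState,
    memory: DeclarativeMemory,
    params: ActivationParams,
    now: float = 0.0,
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
) -> list:
    """Top-k parsing-step chunks legal in ``state``: [(chunk, activation)]."""
    if len(memory) == 0:
        raise ParseError("parse failure: empty memory")
    legal = legal_actions(state)
    if not legal:
        raise ParseError("parse failure: no action is legal in this state")
    idx = np.concatenate([memory.slot_value_indices("action", kind) for kind in sorted(legal)])
    idx = np.sort(idx)
    if idx.size == 0:
        raise ParseError("parse failure: no stored parsing step has a legal action")
    cues = context_cues(extract_features(state, feature_names))
    act = memory.activations(cues, now, params)
    order = idx[np.argsort(-act[idx], kind="stable")]
    top = order[: params.k]
    return [(memory[int(i)], float(act[i])) for i in top]


def decide_step(
    state: ParserState,
    memory: DeclarativeMemory,
    params: ActivationParams,
    now: float = 0.0,
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
):
    """Choose the majority action among the top-k retrieved chunks.

    Returns ``(action, step_activation)`` where the step activation is the
    mean activation of the retrieved chunks.  Ties among equally common
    actions go to the action of the highest-activation chunk.
    """
    retrieved = retrieve_step(state, memory, params, now, feature_names)
    actions = [_chunk_action(c) for c, _ in retrieved]
    tally = Counter(actions)
    best = max(tally.values())
    for a in actions:  # ranked order: first action reaching the max count wins
        if tally[a] == best:
            choice = a
            break
    mean_act = float(np.mean([a for _, a in retrieved]))
    return choice, mean_act


@dataclass
class ParseResult:
    """Outcome of a free parse."""

    trees: tuple  # final stack contents (one tree when complete)
    word_activations: list  # per-word mean retrieval activation
    actions: list
    complete: bool

    @property
    def tree(self) -> Optional[PhraseTree]:
        return self.trees[0] if self.complete else None


def parse_sentence(
    tokens: Sequence,
    memory: DeclarativeMemory,
    params: ActivationParams,
    step_budget_factor: int = 10,
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
) -> ParseResult:
    """Parse left to right by repeated retrieval and majority vote.

    A word's activation record is the mean of the step activations of all
    steps up to and including its shift.  After the queue is exhausted the
    parser keeps reducing until one tree remains or the step budget
    (``step_budget_factor`` x sentence length) is spent, in which case the
    partial result is flagged incomplete.
    """
    if not tokens:
        raise ParseError("empty sentence")
    state = initial_state(tokens)
    _check_pos_known(state, memory)
    n_words = len(state.queue)
    budget = step_budget_factor * n_words
    word_acts: list[float] = []
    pending: list[float] = []
    actions: list[Action] = []
    steps = 0
    while not (len(state.queue) == 0 and len(state.stack) == 1):
        if steps >= budget:
            while len(word_acts) < n_words:
                word_acts.append(float(np.mean(pending)) if pending else float("nan"))
                pending = []
            return ParseResult(state.stack, word_acts, actions, complete=False)
        action, act = decide_step(state, memory, params, feature_names=feature_names)
        state = apply_action(state, action)
        actions.append(action)
        pending.append(act)
        if action.kind == Action.SHIFT:
            word_acts.append(float(np.mean(pending)))
            pending = []
        steps += 1
    return ParseResult(state.stack, word_acts, actions, complete=True)


# ---------------------------------------------------------------------------
# gold-guided mode


def oracle_walk(gold_tree: PhraseTree, now: float = 0.0):
    """Yield (state, gold_action) along the oracle path of a prepared tree."""
    state = initial_state(gold_tree.words())
    for action in oracle_actions(gold_tree):
        yield state, action
        state = apply_action(state, action, now)


def guided_parse(
    tokens: Sequence,
    gold_tree: PhraseTree,
    memory: DeclarativeMemory,
    params: ActivationParams,
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
) -> list:
    """Per-word mean activations with the gold parse as retrieval context.

    At every step the features come from the gold oracle state; the top-k
    retrieval and its mean activation are recorded, and the gold action is
    applied regardless of the majority vote.
    """
    gold_words = [w for w, _, _ in gold_tree.words()]
    words = [t[0] for t in tokens]
    if gold_words != words:
        raise ParseError("gold tree terminals do not match the sentence")
    word_acts: list[float] = []
    pending: list[float] = []
    for state, action in oracle_walk(gold_tree):
        retrieved = retrieve_step(state, memory, params, feature_names=feature_names)
        pending.append(float(np.mean([a for _, a in retrieved])))
        if action.kind == Action.SHIFT:
            word_acts.append(float(np.mean(pending)))
            pending = []
    # reduces after the final shift belong to no word's activation record
    return word_acts


def replay(tree: PhraseTree) -> PhraseTree:
    """Reconstruct a prepared tree by replaying its oracle actions."""
    state = initial_state(tree.words())
    for action in oracle_actions(tree):
        state = apply_action(state, action)
    if len(state.stack) != 1 or state.queue:
        raise ParseError("replay did not terminate in a single tree")
    return state.stack[0]
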