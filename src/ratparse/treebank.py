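"""Bracketed phrase-structure trees: I/O, preprocessing and oracle actions.

Trees come in as Penn-Treebank-style bracketed text.  Before they are usable
for chunk harvesting they are preprocessed (numeric coreference indices
stripped, terminals lemmatized, wh-trace sites turned into gap leaves),
right-factored into binary trees, and annotated with lexical heads by a
Collins-style head-percolation table.  From a prepared tree a unique
bottom-up oracle action sequence (shift / reduce / postulate-gap) is
derived; replaying it from an empty parser state reconstructs the tree.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional
import logging

from .memory_core import (
    Chunk,
    DeclarativeMemory,
    DEFAULT_LIFETIME,
    schedule_from_count,
)

log = logging.getLogger(__name__)

#: reserved decoration for Roark-style intermediate nodes introduced by binarize
BIN_MARK = "|"
#: head atom used for gap leaves
GAP_ATOM = "<gap>"
#: trace prefixes that map to a postulate-gap action (wh-traces by default)
DEFAULT_TRACE_TYPES = ("*T*",)
#: POS tag of empty elements in PTB annotation
NONE_POS = "-NONE-"


class TreebankError(ValueError):
    pass


class PhraseTree:
    """A phrase-structure tree node.

    Leaves are preterminals: ``label`` is the POS tag, ``terminal`` the
    surface word and ``lemma`` its lemmatized form.  Gap leaves stand for
    wh-trace sites; they carry the phrase label of the trace site and no
    terminal.  ``head`` is a ``(lemma, POS)`` pair after head annotation.
    """

    __slots__ = ("label", "children", "terminal", "lemma", "head", "gap")

    def __init__(self, label, children=(), terminal=None, lemma=None, head=None, gap=False):
        self.label = label
        self.children = tuple(children)
        self.terminal = terminal
        self.lemma = lemma
        self.head = head
        self.gap = gap

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def words(self):
        """Surface (word, lemma, POS) triples, skipping gap leaves."""
        return [(l.terminal, l.lemma, l.label) for l in self.leaves() if not l.gap]

    def __eq__(self, other):
        if not isinstance(other, PhraseTree):
            return NotImplemented
        return (
            self.label == other.label
            and self.terminal == other.terminal
            and self.lemma == other.lemma
            and self.head == other.head
            and self.gap == other.gap
            and self.children == other.children
        )

    def __hash__(self):
        return hash((self.label, self.terminal, self.lemma, self.head, self.gap, self.children))

    def __repr__(self):
        return write_tree(self)


# ---------------------------------------------------------------------------
# bracketed text I/O


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def read_trees(text: str) -> list:
    """Parse bracketed trees; several top-level trees are allowed.

    PTB-style outer wrappers ``( (S ...) )`` are spliced away.  Empty
    elements (``-NONE-`` leaves) are preserved for later gap extraction.
    """
    trees: list[PhraseTree] = []
    stack: list[list] = []  # each frame: [label, children]
    line = 1
    pending_label = False
    for m in _TOKEN_RE.finditer(text):
        tok = m.group()
        line = text.count("\n", 0, m.start()) + 1
        if tok == "(":
            stack.append(["", []])
            pending_label = True
        elif tok == ")":
            if not stack:
                raise TreebankError(f"unbalanced brackets: unexpected ')' at line {line}")
            label, children = stack.pop()
            if not children and label:
                # bare category with no children: treat as terminal-less leaf
                node = PhraseTree(label)
            elif len(children) == 1 and isinstance(children[0], str):
                node = PhraseTree(label, terminal=children[0])
            else:
                kids = [c for c in children if isinstance(c, PhraseTree)]
                if len(kids) != len(children):
                    raise TreebankError(f"mixed terminal/non-terminal children at line {line}")
                if label == "":
                    node = kids[0] if len(kids) == 1 else PhraseTree("", kids)
                else:
                    node = PhraseTree(label, kids)
            if stack:
                stack[-1][1].append(node)
            else:
                if node.label == "" and not node.is_leaf:
                    trees.extend(node.children)
                else:
                    trees.append(node)
            pending_label = False
        else:
            if not stack:
                raise TreebankError(f"stray token {tok!r} outside brackets at line {line}")
            if pending_label and not stack[-1][0]:
                stack[-1][0] = tok
                pending_label = False
            else:
                stack[-1][1].append(tok)
    if stack:
        raise TreebankError(f"unbalanced brackets: {len(stack)} unclosed '(' at line {line}")
    return trees


def write_tree(tree: PhraseTree) -> str:
    if tree.gap:
        return f"({tree.label} ({NONE_POS} *T*))"
    if tree.is_leaf:
        return f"({tree.label} {tree.terminal})"
    return "(" + tree.label + " " + " ".join(write_tree(c) for c in tree.children) + ")"


def write_trees(trees: Iterable[PhraseTree]) -> str:
    return "\n".join(write_tree(t) for t in trees) + "\n"


# ---------------------------------------------------------------------------
# preprocessing: index stripping, lemmatization, trace conversion

_INDEX_RE = re.compile(r"([-=]\d+)+$")

#: compact lemma dictionary covering the fixture lexicon plus common
#: irregulars; identity fallback keeps the procedure deterministic.
DEFAULT_LEMMAS = {
    "dances": "dance", "danced": "dance", "dancing": "dance",
    "knows": "know", "knew": "know", "known": "know",
    "sees": "see", "saw": "see", "seen": "see",
    "likes": "like", "liked": "like",
    "falls": "fall", "fell": "fall", "fallen": "fall",
    "barks": "bark", "barked": "bark",
    "runs": "run", "ran": "run", "running": "run",
    "sleeps": "sleep", "slept": "sleep",
    "believes": "believe", "believed": "believe",
    "races": "race", "raced": "race",
    "bites": "bite", "bit": "bite", "bitten": "bite",
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "has": "have", "had": "have", "having": "have",
    "boys": "boy", "girls": "girl", "men": "man", "women": "woman",
    "dogs": "dog", "cats": "cat", "horses": "horse", "stories": "story",
    "friends": "friend", "parks": "park", "answers": "answer",
    "houses": "house", "barns": "barn", "doctors": "doctor",
}


def lemmatize(word: str, lemma_dict: Optional[dict] = None) -> str:
    d = DEFAULT_LEMMAS if lemma_dict is None else lemma_dict
    w = word.lower()
    return d.get(w, w)


def strip_indices(label: str) -> str:
    """Remove trailing numeric coreference/gap indices (NP-SBJ-1 -> NP-SBJ).

    Function tags (-SBJ, -TMP, ...) are retained; only numeric indices go.
    """
    return _INDEX_RE.sub("", label)


def preprocess(
    tree: PhraseTree,
    lemma_dict: Optional[dict] = None,
    trace_types: tuple = DEFAULT_TRACE_TYPES,
) -> PhraseTree:
    """Clean a raw tree: strip indices, lemmatize, convert wh-traces to gaps.

    A node dominating only a ``-NONE-`` leaf whose terminal starts with one
    of ``trace_types`` becomes a gap leaf carrying that node's label.  Other
    empty elements are deleted (with empty ancestors pruned).
    """

    def rec(node: PhraseTree) -> Optional[PhraseTree]:
        label = strip_indices(node.label)
        if node.is_leaf:
            if node.label == NONE_POS:
                return None  # bare trace; handled by parent or dropped
            return PhraseTree(
                label, terminal=node.terminal, lemma=lemmatize(node.terminal, lemma_dict)
            )
        if (
            len(node.children) == 1
            and node.children[0].is_leaf
            and node.children[0].label == NONE_POS
        ):
            term = node.children[0].terminal or ""
            if any(term.startswith(t) for t in trace_types):
                return PhraseTree(label, gap=True, head=(GAP_ATOM, label))
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        return PhraseTree(label, kids)

    out = rec(tree)
    if out is None:
        raise TreebankError("tree empty after preprocessing")
    return out


# ---------------------------------------------------------------------------
# binarization (right-factored, decorated intermediate labels)


def binarize(tree: PhraseTree) -> PhraseTree:
    """Right-factor n-ary nodes: (A b c d) -> (A b (A| c d)); exact inverse
    is :func:`unbinarize`.  Already-binary trees pass through unchanged."""
    if tree.is_leaf:
        return tree
    kids = [binarize(c) for c in tree.children]
    while len(kids) > 2:
        kids = kids[:-2] + [PhraseTree(tree.label + BIN_MARK, kids[-2:])]
    return PhraseTree(tree.label, kids, head=tree.head)


def unbinarize(tree: PhraseTree) -> PhraseTree:
    if tree.is_leaf:
        return tree
    kids: list[PhraseTree] = []
    for c in tree.children:
        c = unbinarize(c)
        if c.label.endswith(BIN_MARK):
            kids.extend(c.children)
        else:
            kids.append(c)
    return PhraseTree(tree.label, kids, head=tree.head)


# ---------------------------------------------------------------------------
# head annotation


@dataclass(frozen=True)
class HeadRule:
    direction: str  # "left" or "right"
    priorities: tuple


def load_head_rules() -> dict:
    text = resources.files(__package__).joinpath("head_rules.tsv").read_text()
    rules = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cat, direction, prios = line.split("\t")
        rules[cat] = HeadRule(direction, tuple(prios.split()))
    return rules


_HEAD_RULES: Optional[dict] = None


def _rules() -> dict:
    global _HEAD_RULES
    if _HEAD_RULES is None:
        _HEAD_RULES = load_head_rules()
    return _HEAD_RULES


def _base_label(label: str) -> str:
    return label.rstrip(BIN_MARK).split("-")[0].split("=")[0]


def head_child_index(label: str, children, head_rules: Optional[dict] = None) -> int:
    """Index of the head child for a node ``label`` over ``children``."""
    rules = _rules() if head_rules is None else head_rules
    rule = rules.get(_base_label(label))
    if rule is None:
        log.warning("no head rule for category %r; defaulting to rightmost child", label)
        return len(children) - 1
    order = range(len(children)) if rule.direction == "left" else range(len(children) - 1, -1, -1)
    for want in rule.priorities:
        for i in order:
            if _base_label(children[i].label) == want:
                return i
    # decorated intermediate nodes inherit the parent category: try them next
    for i in order:
        if children[i].label.endswith(BIN_MARK):
            return i
    return len(children) - 1


def head_for(label: str, children, head_rules: Optional[dict] = None):
    """Percolated (lemma, POS) head for a new node over ``children``."""
    return children[head_child_index(label, children, head_rules)].head


def annotate_heads(tree: PhraseTree, head_rules: Optional[dict] = None) -> PhraseTree:
    """Annotate every node with its (head lemma, head POS), bottom-up."""
    if tree.is_leaf:
        if tree.gap:
            return PhraseTree(tree.label, gap=True, head=(GAP_ATOM, tree.label))
        return PhraseTree(
            tree.label,
            terminal=tree.terminal,
            lemma=tree.lemma,
            head=(tree.lemma if tree.lemma is not None else tree.terminal, tree.label),
        )
    kids = [annotate_heads(c, head_rules) for c in tree.children]
    return PhraseTree(tree.label, kids, head=head_for(tree.label, kids, head_rules))


def prepare(tree: PhraseTree, lemma_dict: Optional[dict] = None) -> PhraseTree:
    """Full preparation pipeline: preprocess -> binarize -> annotate heads."""
    return annotate_heads(binarize(preprocess(tree, lemma_dict)))


# ---------------------------------------------------------------------------
# actions and the oracle


@dataclass(frozen=True)
class Action:
    """A parsing-step action.

    kind      one of shift / reduce_unary / reduce_binary / postulate_gap
    label     new root category (reduce actions only)
    gap_info  phrase label of the postulated gap site (postulate_gap only)
    """

    kind: str
    label: Optional[str] = None
    gap_info: Optional[str] = None

    SHIFT = "shift"
    REDUCE_UNARY = "reduce_unary"
    REDUCE_BINARY = "reduce_binary"
    POSTULATE_GAP = "postulate_gap"
    KINDS = (SHIFT, REDUCE_UNARY, REDUCE_BINARY, POSTULATE_GAP)

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")
        if (self.label is not None) != (self.kind in (self.REDUCE_UNARY, self.REDUCE_BINARY)):
            raise ValueError("label present iff the action is a reduce")
        if (self.gap_info is not None) != (self.kind == self.POSTULATE_GAP):
            raise ValueError("gap_info present iff the action is postulate_gap")


def oracle_actions(tree: PhraseTree) -> list:
    """Bottom-up post-order action sequence reconstructing ``tree``.

    Requires a prepared (preprocessed, binarized, head-annotated) tree.
    Gap leaves emit postulate_gap; at most two may occur between shifts.
    """
    actions: list[Action] = []

    def rec(node: PhraseTree):
        if node.is_leaf:
            if node.gap:
                actions.append(Action(Action.POSTULATE_GAP, gap_info=node.label))
            else:
                actions.append(Action(Action.SHIFT))
            return
        for c in node.children:
            rec(c)
        if len(node.children) == 1:
            actions.append(Action(Action.REDUCE_UNARY, label=node.label))
        elif len(node.children) == 2:
            actions.append(Action(Action.REDUCE_BINARY, label=node.label))
        else:
            raise TreebankError("oracle infeasible: tree not binarized")

    rec(tree)
    gaps = 0
    for a in actions:
        if a.kind == Action.POSTULATE_GAP:
            gaps += 1
            if gaps > 2:
                raise TreebankError(
                    "oracle infeasible: more than two gaps between shifts"
                )
        elif a.kind == Action.SHIFT:
            gaps = 0
    return actions


# ---------------------------------------------------------------------------
# chunk harvesting


@dataclass(frozen=True)
class FrequencyParams:
    """How corpus step counts become presentation schedules."""

    lifetime: float = DEFAULT_LIFETIME
    exposure_scale: float = 1.0


def collect_chunks(
    trees: Iterable[PhraseTree],
    feature_extractor=None,
    freq_params: FrequencyParams = FrequencyParams(),
    prepared: bool = False,
) -> DeclarativeMemory:
    """Harvest parsing-step chunks from gold trees into declarative memory.

    Every oracle step of every tree yields a chunk whose slots are the
    parser-context features at that step plus the action taken.  Identical
    chunks are merged with summed counts; counts become surrogate
    presentation schedules via :func:`schedule_from_count`.
    """
    from . import parser as _parser  # deferred: parser imports treebank types

    extract = feature_extractor or _parser.extract_features
    counts: Counter = Counter()
    order: dict = {}
    for tree in trees:
        t = tree if prepared else prepare(tree)
        state = _parser.initial_state(t.words())
        for action in oracle_actions(t):
            feats = extract(state)
            # slot-qualified atoms so that cue matching is positional
            slots = {k: _parser.cue_atom(k, v) for k, v in feats.items()}
            slots["action"] = action.kind
            slots["action_label"] = (
                action.label if action.label is not None
                else action.gap_info if action.gap_info is not None
                else "none"
            )
            key = frozenset(slots.items())
            counts[key] += 1
            order.setdefault(key, (len(order), slots))
            state = _parser.apply_action(state, action)
    total = sum(counts.values())
    mem = DeclarativeMemory()
    for key, (_, slots) in sorted(order.items(), key=lambda kv: kv[1][0]):
        mem.add(
            Chunk(
                slots,
                schedule_from_count(
                    counts[key], total, freq_params.lifetime, freq_params.exposure_scale
                ),
                count=counts[key],
            )
        )
    return mem
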