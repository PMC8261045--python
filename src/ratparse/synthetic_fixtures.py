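"""Seeded synthetic inputs: a toy treebank, garden-path minimal pairs, and
synthetic self-paced-reading data generated by the model itself.

The toy grammar emulates the *structure* of natural data the model cares
about — Zipf-skewed lexical frequencies, a local NP-vs-S complement
ambiguity with a controllable continuation bias, and wh-relative clauses
containing a filler-gap dependency — not English content.  Every generator
is a pure function of its seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import treebank as tb
from . import reading_model as rm
from .evaluation import GardenPathPair
from .memory_core import ActivationParams, DeclarativeMemory
from .treebank import FrequencyParams, PhraseTree


# ---------------------------------------------------------------------------
# toy grammar


@dataclass(frozen=True)
class ToyGrammar:
    """A small weighted grammar over S, NP, VP, PP, SBAR and friends.

    ``ambiguity_bias`` is the probability that the locally ambiguous
    context "V + NP..." continues as the frequent analysis (direct object)
    rather than the rare one (a bare sentential complement).
    ``relative_fraction`` is the probability that a tree contains one
    wh-relative clause (hence one trace / postulate-gap action).
    """

    nouns: tuple = (
        ("boy", 30), ("girl", 24), ("man", 18), ("dog", 14), ("cat", 10),
        ("story", 7), ("friend", 5), ("park", 4), ("answer", 3), ("horse", 2),
    )
    verbs_intrans: tuple = (("dances", 20), ("runs", 12), ("sleeps", 8), ("barks", 5))
    verbs_trans: tuple = (("sees", 22), ("likes", 14), ("bites", 6))
    verbs_comp: tuple = (("knows", 18), ("believes", 9))  # take NP or S complements
    determiners: tuple = (("the", 70), ("a", 30))
    prepositions: tuple = (("in", 12), ("with", 8))
    ambiguity_bias: float = 0.7
    relative_fraction: float = 0.2
    p_comp_verb: float = 0.35  # fraction of root VPs headed by a complement verb
    p_that: float = 0.45  # complement VPs with an overt "that" clause (unambiguous)
    p_pp: float = 0.12  # NP modified by a PP
    max_depth: int = 3

    def lexicon_frequencies(self) -> dict:
        """Zipf-ish lemma frequency table for the reading model's lexicon."""
        freq: Counter = Counter()
        groups = (
            self.nouns, self.verbs_intrans, self.verbs_trans, self.verbs_comp,
            self.determiners, self.prepositions, (("who", 6), ("that", 25)),
        )
        for group in groups:
            for word, w in group:
                freq[tb.lemmatize(word)] += w * 40
        return dict(freq)


def _pick(rng: np.random.Generator, items: Sequence) -> str:
    words = [w for w, _ in items]
    weights = np.array([float(c) for _, c in items])
    return words[rng.choice(len(words), p=weights / weights.sum())]


def _leaf(pos: str, word: str) -> PhraseTree:
    return PhraseTree(pos, terminal=word)


def _np(rng, g: ToyGrammar, depth: int, allow_rel: bool) -> PhraseTree:
    det = _leaf("DT", _pick(rng, g.determiners))
    noun = _leaf("NN", _pick(rng, g.nouns))
    if allow_rel:
        # (NP (DT d) (NN n) (SBAR (WHNP (WP who)) (S (NP *T*) VP))) -- ternary,
        # exercising binarization; the trace becomes a postulate-gap action.
        rel_vp = _vp(rng, g, depth + 1, allow_comp=False)
        sbar = PhraseTree(
            "SBAR",
            [
                PhraseTree("WHNP", [_leaf("WP", "who")]),
                PhraseTree("S", [PhraseTree("NP", [_leaf(tb.NONE_POS, "*T*-1")]), rel_vp]),
            ],
        )
        return PhraseTree("NP", [det, noun, sbar])
    if depth < g.max_depth and rng.uniform() < g.p_pp:
        inner = PhraseTree("NP", [det, noun])
        pp = PhraseTree(
            "PP", [_leaf("IN", _pick(rng, g.prepositions)), _np(rng, g, depth + 1, False)]
        )
        return PhraseTree("NP", [inner, pp])
    return PhraseTree("NP", [det, noun])


def _vp(rng, g: ToyGrammar, depth: int, allow_comp: bool = True) -> PhraseTree:
    if allow_comp and depth < g.max_depth and rng.uniform() < g.p_comp_verb:
        verb = _leaf("VBZ", _pick(rng, g.verbs_comp))
        if rng.uniform() < g.p_that:
            # frequent and unambiguous: an overt "that" clause, disambiguated
            # at the complementizer (the control construction)
            emb = PhraseTree(
                "S", [_np(rng, g, depth + 1, False), _vp(rng, g, depth + 1, allow_comp=False)]
            )
            return PhraseTree("VP", [verb, PhraseTree("SBAR", [_leaf("IN", "that"), emb])])
        # locally ambiguous onset "V the N ...": continues as the frequent
        # analysis (plain direct object) with probability = ambiguity_bias
        if rng.uniform() < g.ambiguity_bias:
            return PhraseTree("VP", [verb, _np(rng, g, depth + 1, False)])
        # rare continuation: bare sentential complement (the garden-path source)
        emb = PhraseTree(
            "S", [_np(rng, g, depth + 1, False), _vp(rng, g, depth + 1, allow_comp=False)]
        )
        return PhraseTree("VP", [verb, emb])
    if rng.uniform() < 0.55:
        return PhraseTree("VP", [_leaf("VBZ", _pick(rng, g.verbs_intrans))])
    return PhraseTree("VP", [_leaf("VBZ", _pick(rng, g.verbs_trans)), _np(rng, g, depth + 1, False)])


def sample_tree(rng: np.random.Generator, grammar: ToyGrammar) -> PhraseTree:
    with_rel = rng.uniform() < grammar.relative_fraction
    subj = _np(rng, grammar, 1, allow_rel=with_rel)
    return PhraseTree("S", [subj, _vp(rng, grammar, 1)])


def toy_treebank(
    grammar: Optional[ToyGrammar] = None, n_trees: int = 100, seed: int = 0
) -> str:
    """A seeded bracketed treebank, one tree per line; byte-reproducible."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    g = grammar or ToyGrammar()
    rng = np.random.default_rng(seed)
    return tb.write_trees(sample_tree(rng, g) for _ in range(n_trees))


# ---------------------------------------------------------------------------
# garden-path fixture


def gardenpath_fixture(ambiguity_bias: float = 0.9, seed: int = 0, n_trees: int = 300):
    """A biased treebank plus minimal pairs whose garden-path member needs
    the rare continuation.

    With ``ambiguity_bias`` close to 1 the harvested memory strongly prefers
    the direct-object analysis of "V + NP", so the bare-S garden-path member
    loses activation at the disambiguating embedded verb relative to its
    overtly complementized control.
    """
    if ambiguity_bias == 0.5:
        raise ValueError("bias 0.5 provides no preference; pick a biased value")
    g = ToyGrammar(ambiguity_bias=ambiguity_bias, relative_fraction=0.1)
    text = toy_treebank(g, n_trees=n_trees, seed=seed)
    pairs = [
        GardenPathPair(
            id="np_s_complement",
            garden_path=(
                ("the", "DT"), ("man", "NN"), ("knows", "VBZ"),
                ("the", "DT"), ("boy", "NN"), ("likes", "VBZ"),
                ("the", "DT"), ("cat", "NN"),
            ),
            control=(
                ("the", "DT"), ("man", "NN"), ("knows", "VBZ"), ("that", "IN"),
                ("the", "DT"), ("boy", "NN"), ("likes", "VBZ"),
                ("the", "DT"), ("cat", "NN"),
            ),
            critical_word="likes",
        ),
        GardenPathPair(
            id="np_s_complement_2",
            garden_path=(
                ("the", "DT"), ("girl", "NN"), ("believes", "VBZ"),
                ("the", "DT"), ("dog", "NN"), ("sees", "VBZ"),
                ("the", "DT"), ("horse", "NN"),
            ),
            control=(
                ("the", "DT"), ("girl", "NN"), ("believes", "VBZ"), ("that", "IN"),
                ("the", "DT"), ("dog", "NN"), ("sees", "VBZ"),
                ("the", "DT"), ("horse", "NN"),
            ),
            critical_word="sees",
        ),
    ]
    return text, pairs


def harvest(text: str, freq_params: FrequencyParams = FrequencyParams()) -> DeclarativeMemory:
    """Read a bracketed treebank and harvest parsing-step chunks."""
    return tb.collect_chunks(tb.read_trees(text), freq_params=freq_params)


# ---------------------------------------------------------------------------
# synthetic self-paced-reading corpus


def _ngram_logprobs(sentences: Sequence) -> tuple:
    """Toy add-one-smoothed bigram/trigram log-probabilities per token."""
    uni: Counter = Counter()
    bi: Counter = Counter()
    tri: Counter = Counter()
    seqs = [["<s>", "<s>"] + [w for w, *_ in sent] for sent in sentences]
    for seq in seqs:
        for i in range(2, len(seq)):
            uni[seq[i]] += 1
            bi[(seq[i - 1], seq[i])] += 1
            tri[(seq[i - 2], seq[i - 1], seq[i])] += 1
    v = len(uni) + 1
    total = sum(uni.values())
    out_bi, out_tri, out_uni = [], [], []
    for seq in seqs:
        sb, st, su = [], [], []
        for i in range(2, len(seq)):
            su.append(math.log((uni[seq[i]] + 1) / (total + v)))
            ctx1 = sum(c for (a, _), c in bi.items() if a == seq[i - 1])
            sb.append(math.log((bi[(seq[i - 1], seq[i])] + 1) / (ctx1 + v)))
            ctx2 = sum(c for (a, b, _), c in tri.items() if (a, b) == (seq[i - 2], seq[i - 1]))
            st.append(math.log((tri[(seq[i - 2], seq[i - 1], seq[i])] + 1) / (ctx2 + v)))
        out_uni.append(su)
        out_bi.append(sb)
        out_tri.append(st)
    return out_uni, out_bi, out_tri


def synth_spr_corpus(
    trees: Sequence[PhraseTree],
    parse_memory: DeclarativeMemory,
    lexicon: DeclarativeMemory,
    true_F: float,
    true_f: float,
    noise_sd_ms: float = 20.0,
    seed: int = 0,
    n_stories: int = 2,
    act_params: Optional[ActivationParams] = None,
    timing: Optional[rm.TimingParams] = None,
):
    """Simulate reading of ``trees`` and add seeded Normal RT noise.

    ``trees`` are *prepared* gold trees (one sentence each), split evenly
    into ``n_stories`` stories.  Observed RT = simulated RT + Normal(0,
    ``noise_sd_ms``).  Returns ``(table, context)``; the table carries the
    schema :func:`~ratparse.fitting.prepare_rt_data` expects plus toy
    unigram/bigram/trigram columns and word lengths.
    """
    base = act_params or ActivationParams()
    params = ActivationParams(
        d=base.d, W=base.W, S_max=base.S_max, F=true_F, f=true_f,
        tau=base.tau, k=base.k, per_cue_weight_mode=base.per_cue_weight_mode,
    )
    timing = timing or rm.TimingParams()
    sentences = [t.words() for t in trees]
    per_story = math.ceil(len(trees) / n_stories)
    stories = [1 + i // per_story for i in range(len(trees))]
    table, ctx = rm.simulate_text(
        sentences, trees, parse_memory, lexicon, params, timing, stories=stories
    )
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd_ms, size=len(table)) if noise_sd_ms > 0 else np.zeros(len(table))
    )
    table = table.copy()
    table["rt_ms"] = table["predicted_rt_ms"] + noise
    table["nchar"] = table["word"].str.len()
    uni, bi, tri = _ngram_logprobs(sentences)
    table["log_freq"] = [x for s in uni for x in s]
    table["log_bigram"] = [x for s in bi for x in s]
    table["log_trigram"] = [x for s in tri for x in s]
    return table, ctx
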