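"""Word-by-word simulation of self-paced reading.

On each word the procedural system fires a fixed sequence of processes:
attend the word (50 ms), retrieve its lexical entry, retrieve parsing steps
until a shift is found, retrieve the wh-filler whenever a gap is postulated,
and press the key (150 ms) — the attention shift to the next word runs
concurrently with the key press and adds no time.  Every
declarative-memory process costs a procedural firing ``r`` (33 ms) plus the
retrieval latency F*exp(-f*A) of the retrieved chunk, so a word's RT is

    RT = t_attend + (r + T_lex) + sum_steps (r + T_step)
         + sum_gaps (r + T_wh) + t_keypress.

The clock runs continuously within a sentence (driving wh-filler decay) and
resets at sentence boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import parser as _parser
from .memory_core import (
    ActivationParams,
    Chunk,
    DeclarativeMemory,
    PresentationSchedule,
    base_level,
    retrieval_latency,
    schedule_from_count,
    DEFAULT_LIFETIME,
)
from .treebank import Action, FrequencyParams, PhraseTree


@dataclass(frozen=True)
class TimingParams:
    """Fixed time costs of the reading model, in seconds.

    r           procedural process-firing cost (33 ms)
    t_attend    visual attention to a word (50 ms)
    t_keypress  motor key press, concurrent with the attention shift (150 ms)
    likelihood_sd  RT noise standard deviation used for fitting (ms)
    """

    r: float = 0.033
    t_attend: float = 0.050
    t_keypress: float = 0.150
    likelihood_sd: float = 20.0

    def __post_init__(self):
        if min(self.r, self.t_attend, self.t_keypress, self.likelihood_sd) <= 0:
            raise ValueError("timing parameters must be positive")


# ---------------------------------------------------------------------------
# lexicon


def build_lexicon(
    frequencies: Mapping[str, int],
    freq_params: FrequencyParams = FrequencyParams(),
) -> DeclarativeMemory:
    """Frequency-derived lexical chunks, one per lemma."""
    total = sum(frequencies.values())
    mem = DeclarativeMemory()
    for lemma in sorted(frequencies):
        count = frequencies[lemma]
        mem.add(
            Chunk(
                {"lemma": lemma, "kind": "word"},
                schedule_from_count(count, total, freq_params.lifetime, freq_params.exposure_scale),
                count=count,
            )
        )
    return mem


def lexical_activation(
    lemma: str,
    lexicon: DeclarativeMemory,
    params: ActivationParams,
    now: float = 0.0,
) -> float:
    """Base-level activation of a word's lexical chunk (no spreading).

    Unknown lemmas get the smoothing floor of a single presentation over the
    default lifetime.
    """
    idx = lexicon.slot_value_indices("lemma", lemma)
    if idx.size:
        sched = lexicon[int(idx[0])].schedule
    else:
        sched = PresentationSchedule(n=1, span=DEFAULT_LIFETIME)
    return base_level(sched, now, params.d)


def lexical_latency(
    lemma: str,
    lexicon: DeclarativeMemory,
    params: ActivationParams,
    now: float = 0.0,
) -> float:
    return retrieval_latency(lexical_activation(lemma, lexicon, params, now), params)


# ---------------------------------------------------------------------------
# wh-dependent retrieval


def wh_activation(filler_schedule: PresentationSchedule, now: float, params: ActivationParams) -> float:
    return base_level(filler_schedule, now, params.d)


def wh_latency(filler_encoding_time: float, now: float, params: ActivationParams) -> float:
    """Retrieval latency of a wh-filler encoded at ``filler_encoding_time``.

    Strictly increasing in the filler-gap distance ``now - encoding_time``.
    """
    if now <= filler_encoding_time:
        raise ValueError("non-positive age: gap precedes the filler encoding")
    sched = PresentationSchedule(times=(filler_encoding_time,))
    return retrieval_latency(base_level(sched, now, params.d), params)


# ---------------------------------------------------------------------------
# timing contract


def simulate_word(
    lex_latency_s: float,
    step_latencies_s: Sequence[float],
    wh_latencies_s: Sequence[float] = (),
    timing: TimingParams = TimingParams(),
):
    """Apply the per-word timing contract; returns (rt_ms, components_ms).

    The attention shift to the next word fires concurrently with the key
    press and contributes no time.
    """
    comp = {
        "attend_ms": timing.t_attend * 1000.0,
        "lexical_ms": (timing.r + lex_latency_s) * 1000.0,
        "steps_ms": sum(timing.r + t for t in step_latencies_s) * 1000.0,
        "wh_ms": sum(timing.r + t for t in wh_latencies_s) * 1000.0,
        "keypress_ms": timing.t_keypress * 1000.0,
    }
    return sum(comp.values()), comp


# ---------------------------------------------------------------------------
# corpus simulation (gold-guided)


@dataclass
class WordTrace:
    """Per-word record of one simulated reading step."""

    story: int
    sentence: int
    position: int  # 1-based position in the sentence
    word: str
    lemma: str
    rt_ms: float
    components: dict
    lexical_activation: float
    step_activations: list
    wh_activations: list
    n_steps: int
    wh_flag: bool

    @property
    def mean_activation(self) -> float:
        return float(np.mean(self.step_activations)) if self.step_activations else float("nan")


@dataclass
class SimulationContext:
    """Cached activations from one guided simulation.

    RTs at new latency parameters are recomputed as
    ``rt = fixed + 1000 * F * sum(exp(-f * A))`` over each word's retrieval
    events; the fixed costs and the activations are frozen at the reference
    run.  Used to make the fitting likelihood cheap.
    """

    fixed_ms: np.ndarray  # per word
    event_word: np.ndarray  # retrieval event -> word row index
    event_activation: np.ndarray

    def predicted_rt_ms(self, F: float, f: float) -> np.ndarray:
        lat = F * np.exp(-f * self.event_activation)
        rts = self.fixed_ms.copy()
        np.add.at(rts, self.event_word, 1000.0 * lat)
        return rts

    def subset(self, rows: np.ndarray) -> "SimulationContext":
        rows = np.asarray(rows)
        keep = np.isin(self.event_word, rows)
        remap = -np.ones(self.fixed_ms.size, dtype=np.intp)
        remap[rows] = np.arange(rows.size)
        return SimulationContext(
            self.fixed_ms[rows], remap[self.event_word[keep]], self.event_activation[keep]
        )

    @property
    def n_words(self) -> int:
        return int(self.fixed_ms.size)


def simulate_sentence(
    tokens: Sequence,
    gold_tree: PhraseTree,
    parse_memory: DeclarativeMemory,
    lexicon: DeclarativeMemory,
    act_params: ActivationParams,
    timing: TimingParams = TimingParams(),
    story: int = 1,
    sentence: int = 1,
) -> list:
    """Simulate the self-paced reading of one sentence (gold-guided).

    The clock starts at 0 and advances by every process as it fires, so the
    wh-filler's decay reflects the simulated time between its encoding and
    the gap site.
    """
    words = [t[0] for t in tokens]
    gold_words = [w for w, _, _ in gold_tree.words()]
    if words != gold_words:
        raise _parser.ParseError("sentence/tree alignment mismatch")
    clock = 0.0
    traces: list[WordTrace] = []
    walk = list(_parser.oracle_walk(gold_tree))
    # group oracle steps by word: steps up to and including each shift;
    # steps after the final shift are folded into the last word.
    groups: list[list] = [[]]
    for state, action in walk:
        groups[-1].append((state, action))
        if action.kind == Action.SHIFT:
            groups.append([])
    trailing = groups.pop()
    if trailing:
        groups[-1].extend(trailing)

    filler_schedules: dict[int, PresentationSchedule] = {}

    for w_idx, group in enumerate(groups):
        word, lemma, pos = (
            tokens[w_idx] if len(tokens[w_idx]) == 3 else (words[w_idx], None, tokens[w_idx][1])
        )
        if lemma is None:
            lemma = gold_tree.words()[w_idx][1]
        clock += timing.t_attend
        lex_act = lexical_activation(lemma, lexicon, act_params, clock)
        lex_lat = retrieval_latency(lex_act, act_params)
        clock += timing.r + lex_lat
        step_acts: list[float] = []
        step_lats: list[float] = []
        wh_acts: list[float] = []
        wh_lats: list[float] = []
        for state, action in group:
            retrieved = _parser.retrieve_step(state, parse_memory, act_params, now=clock)
            a = float(np.mean([x for _, x in retrieved]))
            lat = retrieval_latency(a, act_params)
            step_acts.append(a)
            step_lats.append(lat)
            clock += timing.r + lat
            next_state = _parser.apply_action(state, action, now=clock)
            if action.kind == Action.SHIFT and len(next_state.fillers) > len(state.fillers):
                fid = len(next_state.fillers) - 1
                filler_schedules[fid] = PresentationSchedule(times=(clock,))
            if action.kind == Action.POSTULATE_GAP:
                if not state.fillers:
                    raise _parser.ParseError("gap postulated with no registered filler")
                fid = len(state.fillers) - 1
                sched = filler_schedules.setdefault(
                    fid, PresentationSchedule(times=(state.fillers[fid].encoding_time,))
                )
                a_wh = base_level(sched, clock, act_params.d)
                lat_wh = retrieval_latency(a_wh, act_params)
                wh_acts.append(a_wh)
                wh_lats.append(lat_wh)
                clock += timing.r + lat_wh
                # a successful retrieval re-presents the filler chunk
                filler_schedules[fid] = sched.with_presentation(clock)
        clock += timing.t_keypress
        rt_ms, comp = simulate_word(lex_lat, step_lats, wh_lats, timing)
        traces.append(
            WordTrace(
                story=story,
                sentence=sentence,
                position=w_idx + 1,
                word=word,
                lemma=lemma,
                rt_ms=rt_ms,
                components=comp,
                lexical_activation=lex_act,
                step_activations=step_acts,
                wh_activations=wh_acts,
                n_steps=len(group),
                wh_flag=bool(wh_acts),
            )
        )
    return traces


def simulate_text(
    sentences: Sequence,
    gold_trees: Sequence,
    parse_memory: DeclarativeMemory,
    lexicon: DeclarativeMemory,
    act_params: ActivationParams,
    timing: TimingParams = TimingParams(),
    stories: Optional[Sequence[int]] = None,
):
    """Simulate a text sentence by sentence; the clock resets per sentence.

    ``sentences`` is a list of token lists; ``stories`` optionally assigns a
    story id per sentence (default: all story 1).  Returns ``(table,
    context)`` — a per-word DataFrame and the :class:`SimulationContext`
    cache for fitting.
    """
    if len(sentences) != len(gold_trees):
        raise ValueError("sentence/tree alignment mismatch")
    if stories is None:
        stories = [1] * len(sentences)
    all_traces: list[WordTrace] = []
    sent_counter: dict[int, int] = {}
    for toks, tree, story in zip(sentences, gold_trees, stories):
        sent_counter[story] = sent_counter.get(story, 0) + 1
        all_traces.extend(
            simulate_sentence(
                toks, tree, parse_memory, lexicon, act_params, timing,
                story=story, sentence=sent_counter[story],
            )
        )
    rows = []
    event_word: list[int] = []
    event_act: list[float] = []
    fixed = np.empty(len(all_traces))
    zone_counter: dict[int, int] = {}
    for i, tr in enumerate(all_traces):
        zone_counter[tr.story] = zone_counter.get(tr.story, 0) + 1
        n_events = 1 + len(tr.step_activations) + len(tr.wh_activations)
        fixed[i] = (timing.t_attend + timing.t_keypress + timing.r * n_events) * 1000.0
        for a in [tr.lexical_activation] + tr.step_activations + tr.wh_activations:
            event_word.append(i)
            event_act.append(a)
        rows.append(
            {
                "story": tr.story,
                "sentence": tr.sentence,
                "zone": zone_counter[tr.story],
                "position": tr.position,
                "word": tr.word,
                "lemma": tr.lemma,
                "n_steps": tr.n_steps,
                "n_wh": len(tr.wh_activations),
                "mean_activation": tr.mean_activation,
                "lexical_activation": tr.lexical_activation,
                "wh_flag": tr.wh_flag,
                "attend_ms": tr.components["attend_ms"],
                "lexical_ms": tr.components["lexical_ms"],
                "steps_ms": tr.components["steps_ms"],
                "wh_ms": tr.components["wh_ms"],
                "keypress_ms": tr.components["keypress_ms"],
                "predicted_rt_ms": tr.rt_ms,
            }
        )
    table = pd.DataFrame(rows)
    ctx = SimulationContext(
        fixed_ms=fixed,
        event_word=np.asarray(event_word, dtype=np.intp),
        event_activation=np.asarray(event_act),
    )
    return table, ctx
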