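"""ACT-R declarative memory: activation calculus and retrieval.

Chunks are slot->value records.  The activation of a chunk is the log-odds
that it is needed now, estimated as the sum of

* base-level activation  B = ln( sum_k t_k^-d )  -- history (recency and
  frequency of the chunk's presentations), and
* spreading activation   S = sum_j w_j * S_ji    -- context, where a cue j
  present in the cognitive context boosts every chunk that carries j as a
  slot value by S_ji = S_max - ln(fan_j).

Activation maps to retrieval latency through T = F * exp(-f * A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

Atom = Union[str, int]

#: reserved atom for absent feature values; never spreads activation
NONE_ATOM = "none"

SECONDS_PER_YEAR = 365.25 * 24 * 3600.0
#: default assumed exposure lifetime for corpus-frequency chunks (15 years)
DEFAULT_LIFETIME = 15.0 * SECONDS_PER_YEAR


# ---------------------------------------------------------------------------
# presentation schedules and base-level activation


@dataclass(frozen=True)
class PresentationSchedule:
    """When a chunk was presented (created or successfully re-used).

    Either an explicit, strictly increasing tuple of timestamps on the
    simulation clock, or a closed-form surrogate ``(n, span)`` standing for
    ``n`` presentations spread uniformly over the last ``span`` seconds —
    the form used for corpus-frequency-derived chunks.
    """

    times: Optional[tuple] = None
    n: Optional[int] = None
    span: Optional[float] = None

    def __post_init__(self):
        if self.times is not None:
            ts = tuple(float(t) for t in self.times)
            if len(ts) == 0:
                raise ValueError("no presentations")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("presentation times must be strictly increasing")
            object.__setattr__(self, "times", ts)
        else:
            if self.n is None or self.span is None:
                raise ValueError("no presentations")
            if self.n < 1:
                raise ValueError("surrogate schedule needs n >= 1")
            if self.span <= 0:
                raise ValueError("surrogate schedule needs span > 0")

    @property
    def is_surrogate(self) -> bool:
        return self.times is None

    def with_presentation(self, t: float) -> "PresentationSchedule":
        """Return a schedule extended by one presentation at time ``t``."""
        if self.is_surrogate:
            return replace(self, n=self.n + 1)
        return PresentationSchedule(times=self.times + (float(t),))


def base_level(schedule: PresentationSchedule, now: float = 0.0, d: float = 0.5) -> float:
    """Base-level activation  B = ln( sum_k (now - t_k)^-d ).

    For the surrogate form, n presentations uniformly spread over ``span``
    give the closed form  B = ln( n * span^-d / (1 - d) ), independent of
    ``now`` (the span is measured up to the moment of retrieval).
    """
    if schedule.is_surrogate:
        if d >= 1.0:
            raise ValueError("surrogate closed form requires d < 1")
        return math.log(schedule.n * schedule.span ** (-d) / (1.0 - d))
    ages = now - np.asarray(schedule.times)
    if np.any(ages <= 0):
        raise ValueError("non-positive age: presentation at or after retrieval time")
    return float(np.log(np.sum(ages ** (-d))))


def schedule_from_count(
    corpus_count: int,
    corpus_total: int,
    lifetime: float = DEFAULT_LIFETIME,
    exposure_scale: float = 1.0,
) -> PresentationSchedule:
    """Turn a corpus frequency into a surrogate presentation schedule.

    ``corpus_count`` occurrences observed out of ``corpus_total`` are mapped
    to ``round(corpus_count * exposure_scale)`` presentations spread over a
    ``lifetime`` of exposure.  Deterministic; the caller decides smoothing
    for unseen items.
    """
    if corpus_count < 1:
        raise ValueError("unseen item")
    if corpus_total < corpus_count:
        raise ValueError("corpus_total must be >= corpus_count")
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    n = max(1, round(corpus_count * exposure_scale))
    return PresentationSchedule(n=n, span=lifetime)


# ---------------------------------------------------------------------------
# parameters and chunks


@dataclass(frozen=True)
class ActivationParams:
    """Free parameters of the activation calculus.

    d       decay exponent of base-level activation (ACT-R default 0.5)
    W       source-activation weight on the context component
    S_max   maximum associative strength (kept large so S_ji stays positive)
    F, f    latency factor (s) and latency exponent mapping A to T
    tau     optional retrieval threshold; chunks below it are not retrieved
    k       retrieval set size (majority vote over the top k)
    """

    d: float = 0.5
    W: float = 1.0
    S_max: float = 20.0
    F: float = 1.0
    f: float = 1.0
    tau: Optional[float] = None
    k: int = 3
    per_cue_weight_mode: str = "undivided"  # or "divided_by_n_cues"
    noise_scale: float = 0.0  # logistic activation noise; off by default

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.W < 0:
            raise ValueError("W must be >= 0")
        if self.S_max <= 0:
            raise ValueError("S_max must be > 0")
        if self.F <= 0 or self.f <= 0:
            raise ValueError("F and f must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.per_cue_weight_mode not in ("undivided", "divided_by_n_cues"):
            raise ValueError("unknown per_cue_weight_mode")


class Chunk:
    """An immutable slot->value record with a presentation schedule.

    ``count`` is the number of merged identical presentations when the chunk
    was harvested from a corpus (identical chunks are deduplicated).
    """

    __slots__ = ("slots", "schedule", "count", "_key")

    def __init__(self, slots: Mapping[str, Atom], schedule: PresentationSchedule, count: int = 1):
        if count < 1:
            raise ValueError("count must be >= 1")
        slots = dict(slots)
        if any(not isinstance(k, str) for k in slots):
            raise ValueError("slot names must be strings")
        self.slots = slots
        self.schedule = schedule
        self.count = count
        self._key = frozenset(slots.items())

    @property
    def key(self) -> frozenset:
        return self._key

    def values(self):
        return self.slots.values()

    def __repr__(self):
        inner = " ".join(f"{k}={v}" for k, v in sorted(self.slots.items()))
        return f"Chunk({inner}, count={self.count})"


class DeclarativeMemory:
    """A store of chunks with a maintained fan index.

    ``fan(v)`` is the number of distinct chunks carrying the atom ``v`` among
    their slot values; it drives the associative strength S_ji = S_max -
    ln(fan_j).  Insertion order is preserved and used as the deterministic
    tie-break in retrieval.
    """

    def __init__(self, chunks: Iterable[Chunk] = ()):
        self._chunks: list[Chunk] = []
        self._by_key: dict[frozenset, int] = {}
        self._fan: dict[Atom, int] = {}
        self._incidence_cache: dict[Atom, np.ndarray] = {}
        self._base_cache: dict[float, np.ndarray] = {}
        self._slot_cache: dict[tuple, np.ndarray] = {}
        for c in chunks:
            self.add(c)

    # -- container protocol -------------------------------------------------
    def __len__(self):
        return len(self._chunks)

    def __iter__(self):
        return iter(self._chunks)

    def __getitem__(self, i: int) -> Chunk:
        return self._chunks[i]

    @property
    def chunks(self) -> Sequence[Chunk]:
        return tuple(self._chunks)

    # -- mutation ------------------------------------------------------------
    def add(self, chunk: Chunk) -> None:
        """Insert a chunk; a chunk with identical slots is merged.

        Merging sums counts and unions schedules (concatenated times for
        explicit schedules; summed n for surrogates with equal span).
        """
        idx = self._by_key.get(chunk.key)
        if idx is None:
            self._by_key[chunk.key] = len(self._chunks)
            self._chunks.append(chunk)
            for v in set(chunk.values()):
                self._fan[v] = self._fan.get(v, 0) + 1
        else:
            old = self._chunks[idx]
            self._chunks[idx] = Chunk(
                old.slots, _merge_schedules(old.schedule, chunk.schedule), old.count + chunk.count
            )
        self._incidence_cache.clear()
        self._base_cache.clear()
        self._slot_cache.clear()

    def slot_value_indices(self, slot: str, value: Atom) -> np.ndarray:
        """Indices of chunks whose ``slot`` holds ``value`` (cached)."""
        key = (slot, value)
        arr = self._slot_cache.get(key)
        if arr is None:
            arr = np.fromiter(
                (i for i, c in enumerate(self._chunks) if c.slots.get(slot) == value),
                dtype=np.intp,
            )
            self._slot_cache[key] = arr
        return arr

    def fan(self, value: Atom) -> int:
        return self._fan.get(value, 0)

    def recount_fan(self) -> dict:
        """Recompute the fan index from scratch (consistency check)."""
        fresh: dict[Atom, int] = {}
        for c in self._chunks:
            for v in set(c.values()):
                fresh[v] = fresh.get(v, 0) + 1
        return fresh

    # -- vectorized scoring ----------------------------------------------------
    def _incidence(self, value: Atom) -> np.ndarray:
        arr = self._incidence_cache.get(value)
        if arr is None:
            arr = np.fromiter(
                (i for i, c in enumerate(self._chunks) if value in set(c.values())),
                dtype=np.intp,
            )
            self._incidence_cache[value] = arr
        return arr

    def base_levels(self, now: float, d: float) -> np.ndarray:
        """Base-level activation of every chunk at time ``now``."""
        cached = self._base_cache.get(d)
        if cached is None:
            vals = np.empty(len(self._chunks))
            explicit = []
            for i, c in enumerate(self._chunks):
                if c.schedule.is_surrogate:
                    vals[i] = base_level(c.schedule, 0.0, d)
                else:
                    vals[i] = np.nan
                    explicit.append(i)
            self._base_cache[d] = vals
            cached = vals
        out = cached.copy()
        for i in np.flatnonzero(np.isnan(out)):
            out[i] = base_level(self._chunks[i].schedule, now, d)
        return out

    def activations(
        self,
        context: Iterable[Atom],
        now: float,
        params: ActivationParams,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Total activation of every chunk given the context cues."""
        if not self._chunks:
            raise ValueError("retrieval failure: empty memory")
        act = self.base_levels(now, params.d)
        cues = [c for c in set(context) if c != NONE_ATOM]
        if cues and params.W > 0:
            w = params.W
            if params.per_cue_weight_mode == "divided_by_n_cues":
                w = params.W / len(cues)
            for cue in cues:
                fan_j = self.fan(cue)
                if fan_j == 0:
                    continue
                act[self._incidence(cue)] += w * (params.S_max - math.log(fan_j))
        if params.noise_scale > 0.0 and rng is not None:
            act = act + rng.logistic(0.0, params.noise_scale, size=act.shape)
        return act


def _merge_schedules(a: PresentationSchedule, b: PresentationSchedule) -> PresentationSchedule:
    if a.is_surrogate and b.is_surrogate and a.span == b.span:
        return PresentationSchedule(n=a.n + b.n, span=a.span)
    if not a.is_surrogate and not b.is_surrogate:
        return PresentationSchedule(times=tuple(sorted(set(a.times) | set(b.times))))
    raise ValueError("cannot merge schedules of different forms")


# ---------------------------------------------------------------------------
# activation components on single chunks (reference, non-vectorized surface)


def fan(value: Atom, memory: DeclarativeMemory) -> int:
    """Number of chunks in memory carrying ``value`` among their slot values."""
    return memory.fan(value)


def associative_strength(
    cue: Atom, chunk: Chunk, S_max: float, memory: DeclarativeMemory
) -> float:
    """S_ji = S_max - ln(fan_j) if the cue appears in the chunk, else 0."""
    if S_max <= 0:
        raise ValueError("S_max must be > 0")
    if cue not in set(chunk.values()):
        return 0.0
    fan_j = memory.fan(cue)
    if fan_j < 1:
        fan_j = 1  # a matching cue has fan >= 1 by construction
    return S_max - math.log(fan_j)


def spreading(
    chunk: Chunk,
    context: Iterable[Atom],
    params: ActivationParams,
    memory: DeclarativeMemory,
) -> float:
    """Context component: sum over cues of w_j * S_ji."""
    cues = [c for c in set(context) if c != NONE_ATOM]
    if not cues:
        return 0.0
    w = params.W
    if params.per_cue_weight_mode == "divided_by_n_cues":
        w = params.W / len(cues)
    return sum(w * associative_strength(j, chunk, params.S_max, memory) for j in cues)


def total_activation(
    chunk: Chunk,
    context: Iterable[Atom],
    now: float,
    params: ActivationParams,
    memory: DeclarativeMemory,
) -> float:
    """A_i = B_i + S_i (no noise term by default)."""
    return base_level(chunk.schedule, now, params.d) + spreading(chunk, context, params, memory)


def retrieval_latency(A: float, params: ActivationParams) -> float:
    """T = F * exp(-f * A), in seconds; strictly decreasing in A."""
    return params.F * math.exp(-params.f * A)


def retrieve_top_k(
    memory: DeclarativeMemory,
    context: Iterable[Atom],
    now: float,
    params: ActivationParams,
    candidate_indices: Optional[Sequence[int]] = None,
) -> list:
    """The k highest-activation chunks, descending; stable tie-break.

    ``candidate_indices`` optionally restricts the competition (the parser
    restricts it to chunks whose action is legal in the current state).
    Returns ``[(chunk, activation), ...]``; fewer than k if fewer qualify.
    """
    if len(memory) == 0:
        raise ValueError("retrieval failure: empty memory")
    act = memory.activations(context, now, params)
    if candidate_indices is None:
        idx = np.arange(len(memory))
    else:
        idx = np.asarray(candidate_indices, dtype=np.intp)
        if idx.size == 0:
            return []
    # stable sort on -activation keeps insertion order among exact ties
    order = idx[np.argsort(-act[idx], kind="stable")]
    out = []
    for i in order:
        a = float(act[i])
        if params.tau is not None and a < params.tau:
            continue
        out.append((memory[int(i)], a))
        if len(out) == params.k:
            break
    return out


# ---------------------------------------------------------------------------
# chunk-store text serialization (one chunk per line, tab-separated)

_RESERVED = ("__count", "__n", "__span", "__times")


def write_chunk_store(memory: DeclarativeMemory, fh) -> None:
    """Write one chunk per line: slot=value fields, count, schedule fields."""
    for c in memory:
        fields = [f"{k}={v}" for k, v in sorted(c.slots.items())]
        fields.append(f"__count={c.count}")
        if c.schedule.is_surrogate:
            fields.append(f"__n={c.schedule.n}")
            fields.append(f"__span={c.schedule.span!r}")
        else:
            fields.append("__times=" + ",".join(repr(t) for t in c.schedule.times))
        fh.write("\t".join(fields) + "\n")


def read_chunk_store(fh) -> DeclarativeMemory:
    mem = DeclarativeMemory()
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        slots: dict[str, Atom] = {}
        count, n, span, times = 1, None, None, None
        for fieldtxt in line.split("\t"):
            k, _, v = fieldtxt.partition("=")
            if k == "__count":
                count = int(v)
            elif k == "__n":
                n = int(v)
            elif k == "__span":
                span = float(v)
            elif k == "__times":
                times = tuple(float(x) for x in v.split(","))
            else:
                slots[k] = v
        if times is not None:
            sched = PresentationSchedule(times=times)
        else:
            sched = PresentationSchedule(n=n, span=span)
        mem.add(Chunk(slots, sched, count))
    return mem
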