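"""The activation calculus: decay, fan, spreading, latency, retrieval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ratparse as rp
from ratparse import memory_core as mc


def make_memory(slot_maps, times=(0.0,)):
    mem = rp.DeclarativeMemory()
    for slots in slot_maps:
        mem.add(rp.Chunk(slots, rp.PresentationSchedule(times=times)))
    return mem


# ---------------------------------------------------------------------------
# base-level activation


@pytest.mark.parametrize(
    "ages, d, expected",
    [
        ((1.0,), 0.5, 0.0),                     # ln(1^-0.5) = 0
        ((4.0,), 0.5, -0.6931471805599453),     # ln(4^-0.5)
        ((1.0, 4.0), 0.5, math.log(1.5)),       # ln(1 + 0.5)
    ],
)
def test_base_level_direct_evaluation(ages, d, expected):
    now = 10.0
    sched = rp.PresentationSchedule(times=tuple(now - a for a in sorted(ages, reverse=True)))
    assert rp.base_level(sched, now, d) == pytest.approx(expected, abs=1e-12)


def test_base_level_errors():
    with pytest.raises(ValueError, match="no presentations"):
        rp.PresentationSchedule(times=())
    sched = rp.PresentationSchedule(times=(5.0,))
    with pytest.raises(ValueError, match="non-positive age"):
        rp.base_level(sched, 5.0, 0.5)


@given(
    ages=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=20, unique=True),
    dt=st.floats(0.1, 100.0),
)
@settings(max_examples=50, derandomize=True)
def test_base_level_decays_with_time_and_grows_with_presentations(ages, dt):
    now = 2e4
    times = tuple(sorted(now - a for a in ages))
    sched = rp.PresentationSchedule(times=times)
    b0 = rp.base_level(sched, now)
    assert rp.base_level(sched, now + dt) < b0
    extended = sched.with_presentation(now - 0.05)
    assert rp.base_level(extended, now) > b0


def test_surrogate_schedule_closed_form():
    # ln(n * span^-d / (1-d))
    sched = rp.schedule_from_count(1000, 10**6, lifetime=100.0)
    assert rp.base_level(sched, d=0.5) == pytest.approx(math.log(1000 * 100**-0.5 / 0.5))
    # frequency ratio 100 -> base-level difference ln(100)
    hi = rp.schedule_from_count(1000, 10**6, lifetime=100.0)
    lo = rp.schedule_from_count(10, 10**6, lifetime=100.0)
    assert rp.base_level(hi) - rp.base_level(lo) == pytest.approx(math.log(100))
    # doubling the lifetime lowers base level by d*ln(2)
    long = rp.schedule_from_count(1000, 10**6, lifetime=200.0)
    assert rp.base_level(hi) - rp.base_level(long) == pytest.approx(0.5 * math.log(2))


def test_schedule_from_count_rejects_unseen():
    with pytest.raises(ValueError, match="unseen item"):
        rp.schedule_from_count(0, 100)


@pytest.mark.parametrize("n", [10, 50, 200])
def test_surrogate_matches_even_spacing_within_5_percent(n):
    """The closed form approximates an explicit evenly spaced schedule at
    the corpus-frequency scale (a years-long exposure span)."""
    span = mc.DEFAULT_LIFETIME
    now = span
    ages = (np.arange(n) + 0.5) * span / n  # uniform spread: midpoint ages
    explicit = rp.base_level(rp.PresentationSchedule(times=tuple(np.sort(now - ages))), now)
    surrogate = rp.base_level(rp.PresentationSchedule(n=n, span=span))
    assert abs(surrogate - explicit) / abs(explicit) < 0.05


# ---------------------------------------------------------------------------
# fan and spreading


def test_fan_counts_chunks_including_candidate():
    mem = make_memory([
        {"role": "subject", "number": "plural"},
        {"number": "plural"},
    ])
    assert rp.fan("subject", mem) == 1
    assert rp.fan("plural", mem) == 2
    assert rp.fan("absent", mem) == 0
    assert mem.recount_fan() == {"subject": 1, "plural": 2}


def test_associative_strength():
    mem = make_memory([
        {"role": "subject", "number": "plural"},
        {"number": "plural"},
    ])
    chunk = mem[0]
    assert rp.associative_strength("absent", chunk, 20.0, mem) == 0.0
    assert rp.associative_strength("subject", chunk, 20.0, mem) == 20.0
    assert rp.associative_strength("plural", chunk, 1.0, mem) == pytest.approx(1 - math.log(2))


def test_spreading_worked_example():
    """Two matching cues with fans 1 and 2 at S_max=1, W=1 -> ~1.3069."""
    mem = make_memory([
        {"role": "subject", "number": "plural", "lemma": "student"},
        {"number": "plural", "lemma": "book"},
    ])
    params = rp.ActivationParams(S_max=1.0, W=1.0)
    s = rp.spreading(mem[0], {"subject", "plural"}, params, mem)
    assert s == pytest.approx(2 - math.log(2), abs=1e-12)
    assert rp.spreading(mem[0], set(), params, mem) == 0.0
    # a cue matching no slot contributes nothing
    assert rp.spreading(mem[0], {"subject", "zzz"}, params, mem) == pytest.approx(1.0)


def test_total_activation_and_divided_mode():
    mem = make_memory([
        {"role": "subject", "number": "plural"},
        {"number": "plural"},
    ])
    params = rp.ActivationParams(S_max=1.0, W=1.0)
    now = 1.0
    a = rp.total_activation(mem[0], {"subject", "plural"}, now, params, mem)
    assert a == pytest.approx(0.0 + 2 - math.log(2))
    assert rp.total_activation(mem[0], set(), now, params, mem) == pytest.approx(
        rp.base_level(mem[0].schedule, now, params.d)
    )
    divided = rp.ActivationParams(S_max=1.0, W=1.0, per_cue_weight_mode="divided_by_n_cues")
    a2 = rp.total_activation(mem[0], {"subject", "plural"}, now, divided, mem)
    assert a2 == pytest.approx((2 - math.log(2)) / 2)


# ---------------------------------------------------------------------------
# latency


@pytest.mark.parametrize(
    "A, F, f, expected",
    [
        (0.0, 1.0, 1.0, 1.0),
        (2 - math.log(2), 1.0, 1.0, 0.2706705664732254),
        (2.0, 0.0139, 0.661, 0.0139 * math.exp(-0.661 * 2)),
    ],
)
def test_retrieval_latency(A, F, f, expected):
    params = rp.ActivationParams(F=F, f=f)
    assert rp.retrieval_latency(A, params) == pytest.approx(expected, rel=1e-9)


@given(a1=st.floats(-10, 10), a2=st.floats(-10, 10))
@settings(max_examples=50, derandomize=True)
def test_latency_strictly_decreasing_in_activation(a1, a2):
    params = rp.ActivationParams(F=0.5, f=0.7)
    if a1 + 1e-9 < a2:  # resolvable difference in float arithmetic
        assert rp.retrieval_latency(a1, params) > rp.retrieval_latency(a2, params)


# ---------------------------------------------------------------------------
# retrieval


def brute_force_top_k(mem, context, now, params):
    scored = [
        (i, rp.total_activation(c, context, now, params, mem)) for i, c in enumerate(mem)
    ]
    scored.sort(key=lambda t: -t[1])  # python sort is stable -> insertion order ties
    out = [(mem[i], a) for i, a in scored if params.tau is None or a >= params.tau]
    return out[: params.k]


@pytest.mark.parametrize("seed", range(5))
def test_retrieve_top_k_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    atoms = [f"v{i}" for i in range(12)]
    mem = rp.DeclarativeMemory()
    now = 1000.0
    for i in range(rng.integers(5, 60)):
        slots = {f"s{j}": atoms[rng.integers(len(atoms))] for j in range(rng.integers(1, 6))}
        times = tuple(sorted(rng.uniform(0, now - 1, size=rng.integers(1, 4))))
        mem.add(rp.Chunk(slots, rp.PresentationSchedule(times=times)))
    params = rp.ActivationParams(S_max=5.0, k=3)
    context = set(rng.choice(atoms, size=3, replace=False))
    got = rp.retrieve_top_k(mem, context, now, params)
    want = brute_force_top_k(mem, context, now, params)
    assert [id(c) for c, _ in got] == [id(c) for c, _ in want]
    assert [a for _, a in got] == pytest.approx([a for _, a in want])


def test_retrieve_top_k_edges():
    mem = make_memory([{"a": "x"}, {"a": "x"}, {"b": "y"}], times=(0.0,))
    # identical chunks merged: only 2 remain
    assert len(mem) == 2 and mem[0].count == 2
    params = rp.ActivationParams(k=10)
    out = rp.retrieve_top_k(mem, set(), 1.0, params)
    assert len(out) == 2  # k > |memory| -> whole memory
    with pytest.raises(ValueError, match="retrieval failure"):
        rp.retrieve_top_k(rp.DeclarativeMemory(), set(), 1.0, params)
    # exact ties resolved by insertion order
    tie = rp.retrieve_top_k(mem, set(), 1.0, rp.ActivationParams(k=2))
    assert tie[0][0] is mem[0]


def test_tau_threshold_excludes_low_activation():
    mem = rp.DeclarativeMemory()
    mem.add(rp.Chunk({"a": "x"}, rp.PresentationSchedule(times=(0.0,))))       # age 100
    mem.add(rp.Chunk({"b": "y"}, rp.PresentationSchedule(times=(99.0,))))      # age 1
    params = rp.ActivationParams(k=3, tau=-1.0)
    out = rp.retrieve_top_k(mem, set(), 100.0, params)
    assert len(out) == 1 and out[0][0] is mem[1]


def test_fan_index_consistent_after_many_insertions():
    rng = np.random.default_rng(0)
    mem = rp.DeclarativeMemory()
    atoms = list("abcdefgh")
    for _ in range(300):
        slots = {f"s{j}": atoms[rng.integers(len(atoms))] for j in range(rng.integers(1, 5))}
        mem.add(rp.Chunk(slots, rp.PresentationSchedule(n=1, span=100.0)))
    assert mem.recount_fan() == {a: mem.fan(a) for a in atoms if mem.fan(a)}


def test_chunk_store_roundtrip(memory, tmp_path):
    path = tmp_path / "chunks.tsv"
    with open(path, "w") as fh:
        rp.write_chunk_store(memory, fh)
    with open(path) as fh:
        back = rp.read_chunk_store(fh)
    assert len(back) == len(memory)
    for a, b in zip(memory, back):
        assert a.key == b.key and a.count == b.count
        assert a.schedule == b.schedule
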