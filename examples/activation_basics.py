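"""The activation calculus on a two-chunk memory, by hand.

A chunk *students* was stored 1 s ago; the context carries the cues
{subject, plural}; there is one other plural chunk in memory.  With decay
d=0.5, weight W=1 and maximum associative strength S=1, its activation and
retrieval latency can be checked with a pocket calculator.
"""

import ratparse as rp

mem = rp.DeclarativeMemory()
students = rp.Chunk({"role": "subject", "number": "plural", "lemma": "student"},
                    rp.PresentationSchedule(times=(0.0,)))
mem.add(students)
mem.add(rp.Chunk({"number": "plural", "lemma": "book"},
                 rp.PresentationSchedule(times=(0.0,))))

params = rp.ActivationParams(d=0.5, W=1.0, S_max=1.0, F=1.0, f=1.0)
context = {"subject", "plural"}

B = rp.base_level(students.schedule, now=1.0, d=params.d)
S = rp.spreading(students, context, params, mem)
A = rp.total_activation(students, context, 1.0, params, mem)
T = rp.retrieval_latency(A, params)

print(f"base-level activation  B = ln(1^-0.5)            = {B:.4f}")
print(f"spreading activation   S = (1-ln 1) + (1-ln 2)   = {S:.4f}")
print(f"total activation       A = B + S                 = {A:.4f}")
print(f"retrieval latency      T = exp(-A)               = {T:.4f} s")
print()
print("The chunk is needed (log-odds ~1.31), so retrieval is fast (~271 ms).")
print("Raising the fan of a cue, or letting time pass, slows it down.")
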