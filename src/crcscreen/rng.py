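"""Counter-based random numbers for paired (common-random-number) simulation.

Every stochastic decision in the simulator draws its uniform from a pure
function of ``(individual key, purpose, labels...)``.  The same decision —
"does the stool test at age 53 of person 81724 come back positive?" — therefore
sees the *same* uniform under every strategy, scenario and sensitivity arm,
so differences between runs are within-person and pathwise-coupled wherever
the event structure allows it.  This is the reproducibility contract the
comparative outcomes (life-years gained, incidence/mortality reductions)
rest on.

The generator is splitmix64, a well-studied 64-bit mixing function; it is
deterministic across platforms and needs no state beyond the integer key.
"""

from __future__ import annotations

_MASK = 0xFFFFFFFFFFFFFFFF
_GOLDEN = 0x9E3779B97F4A7C15

# purpose tags: fixed small integers, never reused across meanings
P_DEATH = 1
P_FRAILTY = 2
P_SEX = 3
P_ONSET = 4
P_GROWTH = 5
P_TRANSITION = 6
P_SOJOURN = 7
P_STAGE = 8
P_SURVIVAL = 9
P_STOOL = 10
P_DETECT = 11
P_REACH = 12
P_FALSEPOS = 13
P_COMPLICATION = 14
P_SEGMENT = 15


def _mix(z: int) -> int:
    z = (z ^ (z >> 30)) * 0xBF58476D1CE4E5B9 & _MASK
    z = (z ^ (z >> 27)) * 0x94D049BB133111EB & _MASK
    return z ^ (z >> 31)


def mix_key(*parts: int) -> int:
    """Fold integer parts into a single 64-bit key (order-sensitive)."""
    z = 0
    for p in parts:
        z = _mix((z + (p & _MASK) + _GOLDEN) & _MASK)
    return z


def u01(key: int, *labels: int) -> float:
    """Uniform(0,1) determined entirely by ``key`` and ``labels``.

    The top 53 bits of the mixed key give a double in [0,1); the zero value
    is nudged up so that probability-0 events never fire on u < p tests.
    """
    u = _mix(mix_key(key, *labels)) >> 11
    return (u + 0.5) * (1.0 / 9007199254740992.0)


class CounterStream:
    """A sequential stream of uniforms under one (key, purpose) pair.

    Used where the number of draws is data-dependent (e.g. thinning a
    Poisson process): the counter makes consecutive draws distinct while
    the (key, purpose) prefix keeps streams independent between purposes
    and between individuals.
    """

    __slots__ = ("_key", "_purpose", "_n")

    def __init__(self, key: int, purpose: int):
        self._key = key
        self._purpose = purpose
        self._n = 0

    def u(self) -> float:
        v = u01(self._key, self._purpose, self._n)
        self._n += 1
        return v


def individual_key(seed: int, individual_id: int) -> int:
    """Derive the per-individual substream key from the run seed.

    Two runs with the same seed assign identical keys, so the same person
    sees identical randomness under every strategy and scenario.
    """
    return mix_key(seed, 0x1D, individual_id)
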