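"""Cross-platform reproducible random numbers (multiply-with-carry).

Model generation must produce identical synaptic connectivity on every
machine and for every choice of detection algorithm, so the pipeline does
not use platform library generators.  Instead it uses a multiply-with-carry
(MWC) generator in the Marsaglia family, implemented in pure integer
arithmetic: the state update involves no floating point, so the sequence is
bit-identical across platforms and Python builds.

Recurrence (all in exact integers)::

    t    = A * x + c
    x'   = t mod 2^32          # the 32-bit output word
    c'   = t div 2^32          # the carry

with the full-period "safe prime" multiplier A = 0xffffda61.  Uniform
variates are ``x' / 2^32`` — a single exact float division per draw.

Independent streams are derived from a master seed plus integer indices
(e.g. rule index and overlap identity) through a SplitMix64-style avalanche
mix, so synapse placement inside one overlap volume consumes its own stream
regardless of the order in which overlaps were detected.
"""

from __future__ import annotations

import math
from typing import Iterable, List

__all__ = ["MWC_MULTIPLIER", "mix64", "stream_seed", "MarsagliaMWC"]

#: Multiplier for the 32-bit multiply-with-carry step; A * 2^31 - 1 and
#: A * 2^32 - 1 are prime, giving a period close to 2^63.
MWC_MULTIPLIER = 0xFFFFDA61

_M64 = (1 << 64) - 1


def mix64(z: int) -> int:
    """SplitMix64 finalizer: a 64-bit avalanche permutation."""
    z = (z + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


def stream_seed(master_seed: int, *indices: int) -> int:
    """Derive a 64-bit stream seed from a master seed and integer indices.

    Distinct index tuples map to (overwhelmingly likely) distinct seeds;
    the mapping is pure integer hashing, hence platform independent.
    """
    h = mix64(master_seed & _M64)
    for v in indices:
        h = mix64(h ^ mix64(v & _M64))
    return h


class MarsagliaMWC:
    """32-bit multiply-with-carry generator with exact integer state.

    Parameters
    ----------
    seed
        Any Python integer.  The 64-bit state (x, c) is derived through
        :func:`mix64`; the degenerate absorbing states (x = 0, c = 0) and
        (x = 2^32 - 1, c = A - 1) are avoided by construction.
    """

    __slots__ = ("x", "c", "seed")

    def __init__(self, seed: int) -> None:
        self.seed = seed
        s = mix64(seed & _M64)
        self.x = s & 0xFFFFFFFF
        self.c = (s >> 32) % (MWC_MULTIPLIER - 1)
        if self.x == 0 and self.c == 0:
            self.x = 1

    def next_u32(self) -> int:
        """Advance the state; return the next 32-bit word."""
        t = MWC_MULTIPLIER * self.x + self.c
        self.x = t & 0xFFFFFFFF
        self.c = t >> 32
        return self.x

    def uniform(self) -> float:
        """Next variate, uniform on [0, 1)."""
        t = MWC_MULTIPLIER * self.x + self.c
        self.x = t & 0xFFFFFFFF
        self.c = t >> 32
        return self.x * 2.3283064365386963e-10  # / 2^32, exact constant

    def uniforms(self, n: int) -> List[float]:
        return [self.uniform() for _ in range(n)]

    def uniform_in(self, lo: float, hi: float) -> float:
        return lo + (hi - lo) * self.uniform()

    def poisson(self, lam: float) -> int:
        """Poisson draw with mean ``lam`` via Knuth's product method.

        Exact in distribution; cost is O(lam) uniforms.  Large means are
        decomposed into chunks (a sum of independent Poissons is Poisson)
        to keep ``exp(-lam)`` away from underflow.
        """
        if lam < 0:
            raise ValueError("Poisson mean must be >= 0")
        count = 0
        while lam > 500.0:
            count += self._poisson_knuth(500.0)
            lam -= 500.0
        return count + self._poisson_knuth(lam)

    def _poisson_knuth(self, lam: float) -> int:
        if lam == 0.0:
            return 0
        limit = math.exp(-lam)
        k = 0
        p = self.uniform()
        while p > limit:
            k += 1
            p *= self.uniform()
        return k
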