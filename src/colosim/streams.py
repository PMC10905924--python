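"""Counter-based random substreams for common-random-number (CRN) simulation.

Every random decision in the simulator is addressed by a key
``(cohort_seed, person_id, stream_name, *counters)`` and hashed to a
uniform deviate with a splitmix64 mixing chain.  This gives

* reproducibility — the same key always yields the same deviate;
* stream independence — adding a new named stream never perturbs draws
  from existing streams;
* scenario alignment — a screening offer at age ``a`` consumes the same
  participation deviate under every strategy, so paired scenario
  differences reflect the intervention only.

The implementation uses plain Python integers masked to 64 bits: the
replay engine makes millions of scalar draws, where this is several
times faster than numpy scalar arithmetic.
"""

from __future__ import annotations

import numpy as np

_MASK = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB
_INIT = 0x853C49E6748FEA9B
_U64 = float(1 << 64)

# named streams (stable numeric ids; order must never change)
STREAMS = {
    "mortality": 1,
    "sex": 2,
    "natural_history": 3,
    "participation": 4,
    "test_noise": 5,
    "colonoscopy": 6,
    "complications": 7,
}


def _mix(x: int) -> int:
    """splitmix64 finalizer on 64-bit integers."""
    x = ((x ^ (x >> 30)) * _MIX1) & _MASK
    x = ((x ^ (x >> 27)) * _MIX2) & _MASK
    return x ^ (x >> 31)


def mix_key(*parts: int) -> int:
    """Hash a tuple of non-negative integers into a 64-bit state."""
    h = _INIT
    for p in parts:
        h = _mix(((h + p) * _GOLDEN) & _MASK)
    return h


def u01(*parts: int) -> float:
    """Uniform(0,1) deviate addressed by an integer key tuple.

    The unit interval is open at both ends (0 and 1 are never returned),
    so inverse-CDF transforms are safe.
    """
    return (mix_key(*parts) + 0.5) / _U64


def u01_array(fixed_parts, counters) -> np.ndarray:
    """Vectorized ``u01``: one deviate per entry of ``counters``, equal to
    ``u01(*fixed_parts, c)`` element-wise."""
    base = mix_key(*fixed_parts)
    out = np.empty(len(counters))
    for i, c in enumerate(counters):
        out[i] = (_mix(((base + int(c)) * _GOLDEN) & _MASK) + 0.5) / _U64
    return out


def substream_seed(cohort_seed: int, person_id: int, stream: str) -> int:
    """Seed for a person's named substream, for use with numpy Generators.

    Derived as hash(cohort_seed, person_id, stream): adding streams or
    persons never changes existing seeds.
    """
    return mix_key(cohort_seed, person_id, STREAMS[stream])
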