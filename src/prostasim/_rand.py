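"""Counter-based random substreams.

Every stochastic quantity in the simulator is a pure function of
``(master_seed, person_id, purpose, slot)``.  This gives an exact
common-random-numbers contract: the same person gets identical draws under
every screening strategy, re-running with the same seed reproduces every
output bit-for-bit, and adding a strategy never perturbs another strategy's
randomness.  Streams are derived with the splitmix64 finalizer, which is a
full-period 64-bit mixer with good avalanche behaviour.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_U53 = np.float64(1.0 / (1 << 53))

# purpose tags for independent substreams
PURPOSE_NATURAL_HISTORY = 11
PURPOSE_PARTICIPATION = 23
PURPOSE_SCREEN_TESTS = 37
PURPOSE_PSA_NOISE = 41
PURPOSE_CALIBRATION = 53
PURPOSE_PSA_SA = 67


def _mix(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = (z ^ (z >> np.uint64(30))) * _M1
        z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


def _stream_key(seed: int, person_ids, purpose: int) -> np.ndarray:
    pid = np.asarray(person_ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        h = _mix(np.uint64(seed) + _GAMMA)
        h = _mix(h ^ _mix(pid + _GAMMA))
        key = _mix(h ^ _mix(np.uint64(purpose) * _GAMMA))
    return key


def uniforms(seed: int, person_ids, purpose: int, n_slots: int) -> np.ndarray:
    """Return an ``(n_persons, n_slots)`` matrix of uniforms in (0, 1)."""
    key = _stream_key(seed, person_ids, purpose)
    with np.errstate(over="ignore"):
        slots = (np.arange(1, n_slots + 1, dtype=np.uint64) * _GAMMA)[None, :]
        bits = _mix(key[:, None] + slots)
    u = (bits >> np.uint64(11)).astype(np.float64) * _U53
    # keep draws strictly inside (0, 1) so log/ndtri never see an endpoint
    return np.clip(u, _U53, 1.0 - 1e-16)


def uniform_slot(seed: int, person_ids, purpose: int, slot) -> np.ndarray:
    """Uniforms for a per-person slot index (e.g. keyed by screening age).

    ``slot`` may be a scalar or an array aligned with ``person_ids``; keying
    test draws by age keeps a man's measured PSA at a given age identical
    across strategies that screen him at that age.
    """
    key = _stream_key(seed, person_ids, purpose)
    with np.errstate(over="ignore"):
        s = (np.asarray(slot, dtype=np.uint64) + np.uint64(1)) * _GAMMA
        bits = _mix(key + s)
    u = (bits >> np.uint64(11)).astype(np.float64) * _U53
    return np.clip(u, _U53, 1.0 - 1e-16)


def normals(seed: int, person_ids, purpose: int, n_slots: int) -> np.ndarray:
    return ndtri(uniforms(seed, person_ids, purpose, n_slots))


def exponentials(seed: int, person_ids, purpose: int, n_slots: int) -> np.ndarray:
    return -np.log(uniforms(seed, person_ids, purpose, n_slots))
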