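"""Shared helpers: hierarchical seeding and small statistical primitives."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def spawn_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Split one master seed into ``n`` independent generators.

    Hierarchical spawning (``numpy.random.SeedSequence``) gives every
    stochastic stage its own stream while keeping the whole run
    reproducible from a single integer.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]


def rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))


def wilson_interval(p: np.ndarray, n: int, conf: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion ``p`` observed over ``n`` trials.

    Accepts fractional expected proportions (the neutral fit evaluates it at
    model-predicted occupancies, which are not integer counts / n).
    """
    from scipy.stats import norm

    p = np.asarray(p, dtype=float)
    z = norm.ppf(0.5 + conf / 2.0)
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    lo = np.clip(centre - half, 0.0, 1.0)
    hi = np.clip(centre + half, 0.0, 1.0)
    return lo, hi
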