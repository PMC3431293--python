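"""Small shared helpers: canonical gene pairs and seed derivation."""

from __future__ import annotations

import numpy as np

GenePair = tuple[str, str]


def canonical_pair(a: str, b: str) -> GenePair:
    """Return the unordered pair (a, b) with the lexicographically smaller id first."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-stage integer seeds (< 2**31) from one global seed.

    Uses numpy's SeedSequence spawning so stages are statistically independent
    and each stage can be re-run on its own with its derived seed.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def comb2(n: int) -> int:
    """n choose 2."""
    return n * (n - 1) // 2
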