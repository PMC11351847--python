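"""Small shared helpers: deterministic seeding and rounding conventions."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed.

    Hash-based so that every stage of a run is independently reproducible
    from the single seed recorded in the run log. Result is < 2**31.
    """
    digest = hashlib.sha256(f"{stage}:{int(global_seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def round_half_up(x):
    """Round with ties going away from zero toward +inf (0.5 -> 1).

    numpy's default rounds half to even; population bookkeeping in the
    deer-herd optimizer uses conventional half-up rounding instead.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def as_rng(seed_or_rng):
    """Coerce a seed to a Generator; pass through generator-like objects.

    Anything that is not None or an integer is returned unchanged, which
    lets tests substitute stub generators with scripted draws.
    """
    if seed_or_rng is None or isinstance(seed_or_rng, (int, np.integer)):
        return np.random.default_rng(seed_or_rng)
    return seed_or_rng
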