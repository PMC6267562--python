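"""Small sequence helpers shared across test modules."""

from __future__ import annotations

import random


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate_positions(rng: random.Random, seq: str, n: int) -> str:
    """Substitute ``n`` distinct positions (away from the original base)."""
    out = list(seq)
    for i in rng.sample(range(len(seq)), min(n, len(seq))):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)
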