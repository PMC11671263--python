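"""Small shared helpers: sequence ops, rounding, deterministic RNG streams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables),
    unlike banker's rounding used by the builtin ``round``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_percentage(part: int, whole: int, decimals: int = 2) -> float:
    """100 * part / whole, rounded half-up to ``decimals`` places.

    Raises ``ValueError`` for whole <= 0 or part outside [0, whole].
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not (0 <= part <= whole):
        raise ValueError("part must lie in [0, whole]")
    return round_half_up(100.0 * part / whole, decimals)


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """An independent generator for one named sub-stream of a run seed.

    Keyed on (seed, stream) so adding a stage never perturbs the draws of
    another stage under the same run seed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(stream)])


_BASES = np.array(list(DNA_ALPHABET))


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-base rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    # substitute with one of the three other bases, uniformly
    for i in np.flatnonzero(hit):
        choices = [b for b in DNA_ALPHABET if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)
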