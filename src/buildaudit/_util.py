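"""Small shared helpers: rounding, sequence encoding, RNG sub-streams."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: operator codes used to derive independent RNG sub-streams from one run seed,
#: so adding an operator never reshuffles the draws of another.
RNG_STREAMS = {
    "gene_models": 0,
    "genome": 1,
    "categorical_errors": 2,
    "indels": 3,
    "missing_fill": 4,
    "split_fill": 5,
    "insert_bases": 6,
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the reporting convention used throughout)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numer: float, denom: float, ndigits: int = 1) -> float:
    if denom == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numer / denom, ndigits)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-operator RNG derived from the run seed."""
    return np.random.default_rng([int(seed), RNG_STREAMS[name]])


_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
for i, b in enumerate(b"acgt"):
    _ENC[b] = i


def encode_seq(seq: str) -> np.ndarray:
    """ACGT -> 0..3 as uint8; anything else (N, gaps) -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
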