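"""Small DNA sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"

# uint8 complement lookup for encoded arrays (ASCII codes)
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_TABLE[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes (zero-copy view)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def validate_dna(seq: str, name: str = "sequence", allow_n: bool = False) -> None:
    """Raise ValueError unless *seq* is non-empty uppercase ACGT (optionally N)."""
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    alphabet = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(
            f"{name} contains invalid characters {sorted(bad)!r}; "
            f"expected uppercase {'ACGTN' if allow_n else 'ACGT'}"
        )


def mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Apply i.i.d. per-base substitutions at *rate*; return (mutant, n_substitutions).

    Substitutions always change the base (drawn from the three alternatives).
    """
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    n = int(hit.sum())
    if n == 0:
        return seq, 0
    for i in np.flatnonzero(hit):
        alternatives = [b for b in BASES if b != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return "".join(arr), n
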