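"""Oligonucleotide (k-mer) counting and frequency profiles.

Counting uses a sliding window shifted by a single nucleotide, so a sequence
of length n has n−k+1 windows.  The frequency of a k-mer is its count divided
by n−k+1 (n−1 for dinucleotides, n−2 for trinucleotides).  Windows containing
a non-ACGT character (ambiguity codes) contribute to no count, but the
denominator keeps its nominal value; pass ``denominator="valid"`` to divide
by the number of clean windows instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd

from .errors import ConfigError, GapError, TooShortError

_ACGT = "ACGT"
_CODE = {c: i for i, c in enumerate(_ACGT)}


@lru_cache(maxsize=None)
def all_kmers(k: int) -> tuple[str, ...]:
    """All 4^k oligonucleotides over A/C/G/T in lexicographic order."""
    return tuple("".join(p) for p in product(_ACGT, repeat=k))


def count_kmers(seq: str, k: int) -> dict[str, int]:
    """Count each length-k A/C/G/T word over all single-shift windows.

    Windows containing a character outside {A,C,G,T} are skipped entirely.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if "-" in seq:
        raise GapError("gapped sequence passed to count_kmers; degap first")
    n = len(seq)
    if n < k:
        raise TooShortError(f"sequence of length {n} shorter than k={k}")
    counts: dict[str, int] = {}
    run = 0  # length of current clean run of ACGT characters
    for i, ch in enumerate(seq):
        run = run + 1 if ch in _CODE else 0
        if run >= k:
            w = seq[i - k + 1 : i + 1]
            counts[w] = counts.get(w, 0) + 1
    return counts


@dataclass
class KmerProfile:
    """Per-sequence k-mer frequency vector.

    ``freqs`` maps every one of the 4^k oligonucleotides to a frequency;
    ``vector`` exposes the same values as a numpy array in the lexicographic
    order of :func:`all_kmers`.
    """

    k: int
    freqs: dict[str, float]
    n_windows: int
    seq_length: int
    _vector: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def vector(self) -> np.ndarray:
        if self._vector is None:
            self._vector = np.array([self.freqs[w] for w in all_kmers(self.k)])
        return self._vector


def kmer_frequencies(seq: str, k: int, denominator: str = "length") -> KmerProfile:
    """Convert counts to frequencies.

    ``denominator="length"`` divides by n−k+1 (the nominal window count);
    ``"valid"`` divides by the number of windows free of ambiguity codes.
    """
    counts = count_kmers(seq, k)
    n = len(seq)
    n_valid = sum(counts.values())
    if denominator == "length":
        denom = n - k + 1
    elif denominator == "valid":
        if n_valid == 0:
            raise TooShortError("no valid windows; cannot normalise by valid count")
        denom = n_valid
    else:
        raise ConfigError(f"unknown denominator rule {denominator!r}")
    freqs = {w: counts.get(w, 0) / denom for w in all_kmers(k)}
    return KmerProfile(k=k, freqs=freqs, n_windows=n_valid, seq_length=n)


def profile_table(profiles: dict[str, KmerProfile]) -> pd.DataFrame:
    """Tabulate profiles as sequence_id × 4^k frequency columns."""
    if not profiles:
        return pd.DataFrame()
    ks = {p.k for p in profiles.values()}
    if len(ks) > 1:
        raise ConfigError("profiles mix different k")
    k = ks.pop()
    cols = list(all_kmers(k))
    data = {sid: [p.freqs[w] for w in cols] for sid, p in profiles.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
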