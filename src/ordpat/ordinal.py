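"""Ordinal-pattern (motif) statistics for univariate time series.

A window of ``m`` consecutive samples is symbolised by its *motif*: the
permutation of window positions listed in ascending amplitude order (the
argsort of the window).  For example the window ``(1.7, -0.3, 2.5)`` has
motif ``(1, 0, 2)`` — the smallest value sits at position 1, the next at
position 0, the largest at position 2.  Sliding the window one sample at a
time over a series of length ``N`` yields ``N - m + 1`` motifs whose
normalised histogram is the relative-frequency vector ``p̂``; its Shannon
entropy is the permutation entropy (PE).

Because consecutive windows share ``m - 1`` samples, the rank order of the
shared samples constrains which motif can follow which: most of the
``m! x m!`` motif pairs are *forbidden transitions*.  The admissibility rule
implemented here (:func:`admissible_successors`) derives the allowed pairs
from that overlap argument alone.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TieWarning",
    "InsufficientDataError",
    "FrequencyVector",
    "motif_alphabet",
    "motif_index",
    "extract_motif",
    "ordinal_sequence",
    "motif_sequence",
    "relative_frequencies",
    "permutation_entropy",
    "admissible_successors",
    "successor_indices",
    "admissible_pair_matrix",
]


class TieWarning(UserWarning):
    """Emitted when a window contains tied amplitudes.

    Ties are broken stably (the earlier position ranks lower), which is the
    common convention for ordinal-pattern analysis of quantised real data.
    """


class InsufficientDataError(ValueError):
    """Raised when a series is shorter than the embedding dimension."""


# Canonical m=3 state order: ascending, its reversal-free cycle mates, then
# the descending pair.  This is the conventional q0..q5 labelling used for
# the six-state motif chain and fixes the column order of feature tables.
_M3_ALPHABET = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 1, 0), (2, 0, 1))


@lru_cache(maxsize=None)
def motif_alphabet(m: int) -> tuple[tuple[int, ...], ...]:
    """Ordered tuple of all ``m!`` motifs with a fixed motif <-> index bijection.

    For ``m == 3`` the canonical six-state order is used; for any other
    dimension the motifs are listed lexicographically.
    """
    if m < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {m}")
    if m == 3:
        return _M3_ALPHABET
    return tuple(itertools.permutations(range(m)))


@lru_cache(maxsize=None)
def _index_map(m: int) -> dict[tuple[int, ...], int]:
    return {p: j for j, p in enumerate(motif_alphabet(m))}


def motif_index(motif: Sequence[int]) -> int:
    """Alphabet position of a motif."""
    motif = tuple(int(v) for v in motif)
    try:
        return _index_map(len(motif))[motif]
    except KeyError:
        raise ValueError(f"{motif!r} is not a permutation of 0..{len(motif) - 1}")


def extract_motif(window: Sequence[float]) -> tuple[int, ...]:
    """Motif of a single window: the stable argsort of its amplitudes.

    Tied amplitudes keep their temporal order (earlier position ranks lower)
    and trigger a :class:`TieWarning`.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be a 1-d sequence of length >= 2")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    order = np.argsort(w, kind="stable")
    if np.any(np.diff(w[order]) == 0):
        warnings.warn("tied amplitudes in window; stable tie-break applied", TieWarning, stacklevel=2)
    return tuple(int(i) for i in order)


def _validate_series(x, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if m < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {m}")
    if x.size < m:
        raise InsufficientDataError(
            f"series of length {x.size} is shorter than embedding dimension m={m}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def ordinal_sequence(x, m: int = 3, *, warn_ties: bool = True) -> np.ndarray:
    """Motif index (alphabet position) of every length-``m`` window of ``x``.

    Windows are fully overlapping with stride 1, so the result has
    ``N - m + 1`` entries.
    """
    x = _validate_series(x, m)
    win = sliding_window_view(x, m)
    order = np.argsort(win, axis=1, kind="stable")
    if warn_ties:
        sorted_win = np.take_along_axis(win, order, axis=1)
        n_tied = int(np.count_nonzero(np.any(np.diff(sorted_win, axis=1) == 0, axis=1)))
        if n_tied:
            warnings.warn(
                f"{n_tied} of {win.shape[0]} windows contain tied amplitudes; "
                "stable tie-break applied",
                TieWarning,
                stacklevel=2,
            )
    # encode each permutation row as a base-m integer and map through a LUT
    radix = m ** np.arange(m)
    codes = order @ radix
    lut = np.full(m**m, -1, dtype=np.int64)
    for j, perm in enumerate(motif_alphabet(m)):
        lut[int(np.dot(perm, radix))] = j
    return lut[codes]


def motif_sequence(x, m: int = 3, *, warn_ties: bool = True) -> list[tuple[int, ...]]:
    """Motifs of every window of ``x``, as permutation tuples."""
    alphabet = motif_alphabet(m)
    return [alphabet[j] for j in ordinal_sequence(x, m, warn_ties=warn_ties)]


@dataclass(frozen=True)
class FrequencyVector:
    """Relative-frequency vector of motifs (the normalised motif histogram).

    ``p[j]`` is the fraction of windows whose motif has alphabet index ``j``;
    ``count_total`` is the number of windows tallied (``N - m + 1``).
    """

    p: np.ndarray
    count_total: int
    m: int

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 1 or p.size != math.factorial(self.m):
            raise ValueError(f"expected {math.factorial(self.m)} components, got {p.size}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("components must be non-negative and sum to 1")


def relative_frequencies(x, m: int = 3, *, warn_ties: bool = True) -> FrequencyVector:
    """Normalised motif histogram of a series, in alphabet order."""
    idx = ordinal_sequence(x, m, warn_ties=warn_ties)
    counts = np.bincount(idx, minlength=math.factorial(m))
    return FrequencyVector(p=counts / idx.size, count_total=int(idx.size), m=m)


def permutation_entropy(freqs, *, base: str | int = "natural", normalized: bool = False,
                        m: int | None = None) -> float:
    """Shannon entropy of a motif relative-frequency vector.

    Only strictly positive components contribute.  ``base`` is ``"natural"``
    (nats, the default) or ``2`` (bits); with ``normalized=True`` the value is
    divided by ``log(m!)`` so it lies in [0, 1].

    ``freqs`` may be a :class:`FrequencyVector` or a bare probability vector
    (then ``normalized=True`` requires ``m`` or infers it from the length).
    """
    if isinstance(freqs, FrequencyVector):
        p = freqs.p
        m = freqs.m
    else:
        p = np.asarray(freqs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("frequency vector must be non-negative and sum to 1")
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    if base == 2:
        h /= math.log(2)
    elif base != "natural":
        raise ValueError("base must be 'natural' or 2")
    if normalized:
        if m is None:
            # infer m! from the vector length
            size = p.size
            m = 2
            while math.factorial(m) < size:
                m += 1
            if math.factorial(m) != size:
                raise ValueError("cannot infer embedding dimension from vector length")
        denom = math.log(math.factorial(m))
        if base == 2:
            denom /= math.log(2)
        h /= denom
    return h


def _inverse(perm: tuple[int, ...]) -> tuple[int, ...]:
    inv = [0] * len(perm)
    for rank, pos in enumerate(perm):
        inv[pos] = rank
    return tuple(inv)


def _relative_pattern(ranks: tuple[int, ...]) -> tuple[int, ...]:
    """Collapse a tuple of distinct ranks to its order pattern (0..len-1)."""
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    rel = [0] * len(ranks)
    for r, pos in enumerate(order):
        rel[pos] = r
    return tuple(rel)


@lru_cache(maxsize=None)
def admissible_successors(motif: tuple[int, ...]) -> tuple[tuple[int, ...], ...]:
    """Motifs that can follow ``motif`` in an overlapping window sequence.

    The last ``m - 1`` samples of one window are the first ``m - 1`` samples
    of the next, so a successor is admissible exactly when the rank order of
    its first ``m - 1`` positions matches the rank order of the source's last
    ``m - 1`` positions.  For ``m = 3`` every motif has exactly 3 admissible
    successors (18 admissible pairs out of 36).
    """
    motif = tuple(int(v) for v in motif)
    m = len(motif)
    if sorted(motif) != list(range(m)):
        raise ValueError(f"{motif!r} is not a permutation of 0..{m - 1}")
    suffix = _relative_pattern(_inverse(motif)[1:])
    return tuple(
        cand for cand in motif_alphabet(m)
        if _relative_pattern(_inverse(cand)[:-1]) == suffix
    )


@lru_cache(maxsize=None)
def successor_indices(m: int) -> tuple[tuple[int, ...], ...]:
    """For each alphabet index, the sorted alphabet indices of its admissible successors."""
    alphabet = motif_alphabet(m)
    return tuple(
        tuple(sorted(motif_index(s) for s in admissible_successors(src)))
        for src in alphabet
    )


@lru_cache(maxsize=None)
def admissible_pair_matrix(m: int) -> np.ndarray:
    """Boolean ``m! x m!`` matrix: entry (i, j) is True iff j may follow i."""
    M = math.factorial(m)
    adm = np.zeros((M, M), dtype=bool)
    for i, targets in enumerate(successor_indices(m)):
        adm[i, list(targets)] = True
    adm.setflags(write=False)
    return adm
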