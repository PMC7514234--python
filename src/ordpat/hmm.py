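"""Synthetic series generation from a motif-emitting Markov chain.

Each of the ``m!`` hidden states deterministically emits one motif (ordinal
pattern).  Transitions between states that would violate the window-overlap
constraint are *forbidden* and carry probability zero, so for ``m = 3`` the
6x6 transition matrix has exactly 18 free entries, three per row.  Driving
the chain with random excitation yields a motif sequence, and amplitudes are
then synthesised so that the sliding-window motif sequence of the resulting
real-valued series reproduces the emitted state sequence exactly.

The amplitude law inside an admissible region is immaterial to every ordinal
statistic (only ranks matter); bounded regions are sampled uniformly and
unbounded ones uniformly on an interval of width ``delta`` beyond the
boundary.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .ordinal import admissible_pair_matrix, motif_alphabet

__all__ = [
    "InvalidSequenceError",
    "ReducibleChainWarning",
    "GeneratedSeries",
    "TRIPLE_TARGET_ORDER",
    "validate_triple",
    "build_matrix_from_triple",
    "validate_matrix",
    "stationary_distribution",
    "emit_state_sequence",
    "synthesize_amplitudes",
    "generate_series",
    "generate_dataset",
]


class InvalidSequenceError(ValueError):
    """Raised when a state sequence contains a forbidden transition."""


class ReducibleChainWarning(UserWarning):
    """Emitted when a transition matrix is not irreducible."""


@dataclass(frozen=True)
class GeneratedSeries:
    """A synthetic series together with its ground-truth state sequence."""

    record_id: str
    label: str | None
    amplitudes: np.ndarray
    states: np.ndarray
    initial_state: int
    m: int = 3


def validate_triple(triple) -> np.ndarray:
    """Check a per-state transition triple (three probabilities summing to 1)."""
    t = np.asarray(triple, dtype=float)
    if t.shape != (3,):
        raise ValueError(f"expected three probabilities, got shape {t.shape}")
    if np.any(t < 0) or abs(t.sum() - 1.0) > 1e-9:
        raise ValueError(f"triple {t.tolist()} must be non-negative and sum to 1")
    return t


# Successor listing order used when a shared probability triple is spread
# over each state's three admissible targets (m = 3 only).  States whose
# window overlap (last two samples) is ascending list their successors as
# (q0, q1, q5); descending-overlap states list (q3, q4, q2).  This is the
# row order of the m=3 admissibility table, and it is the convention under
# which swapping the first two triple entries mirrors the process (amplitude
# negation), so e.g. (1/2, 0, 1/2) and (0, 1/2, 1/2) yield stationary motif
# histograms that are exact coordinate permutations of each other.
TRIPLE_TARGET_ORDER = ((0, 1, 5), (3, 4, 2), (0, 1, 5), (0, 1, 5), (3, 4, 2), (3, 4, 2))


def build_matrix_from_triple(triple, m: int = 3) -> np.ndarray:
    """Full transition matrix from one shared triple of probabilities.

    Every state assigns the triple, in order, to its admissible successor
    states listed in the canonical admissibility-table order (see
    :data:`TRIPLE_TARGET_ORDER`); all forbidden entries are 0.  Requires
    each state to have exactly three admissible successors, i.e. ``m = 3``.
    """
    t = validate_triple(triple)
    if m != 3:
        raise ValueError("triple-based construction is defined for m=3 only")
    M = math.factorial(m)
    A = np.zeros((M, M))
    for i, targets in enumerate(TRIPLE_TARGET_ORDER):
        A[i, list(targets)] = t
    return A


def validate_matrix(A, m: int = 3) -> np.ndarray:
    """Check row-stochasticity and that support respects the overlap rule."""
    A = np.asarray(A, dtype=float)
    M = math.factorial(m)
    if A.shape != (M, M):
        raise ValueError(f"expected a {M}x{M} matrix, got {A.shape}")
    if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("rows must be non-negative and sum to 1")
    adm = admissible_pair_matrix(m)
    bad = np.argwhere((A > 0) & ~adm)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"entry ({i}, {j}) is a forbidden transition but has positive probability")
    return A


def _is_irreducible(A: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components((A > 0).astype(np.int8), directed=True, connection="strong")
    return n == 1


def stationary_distribution(A, *, tol: float = 1e-10) -> np.ndarray:
    """A stationary distribution pi with pi @ A = pi, sum(pi) = 1.

    For an irreducible chain this is unique.  Reducible chains are flagged
    with :class:`ReducibleChainWarning` and one valid stationary vector is
    returned (supported on a recurrent class).
    """
    A = np.asarray(A, dtype=float)
    M = A.shape[0]
    if not _is_irreducible(A):
        warnings.warn("transition matrix is reducible; stationary law is not unique",
                      ReducibleChainWarning, stacklevel=2)
    # eigen-solve of A^T at eigenvalue 1
    vals, vecs = np.linalg.eig(A.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    pi /= pi.sum()
    # one refinement pass via the linear system (replace last equation by sum=1)
    B = A.T - np.eye(M)
    B[-1, :] = 1.0
    rhs = np.zeros(M)
    rhs[-1] = 1.0
    try:
        cand = np.linalg.solve(B, rhs)
        if np.all(cand > -1e-12) and np.linalg.norm(cand @ A - cand) < np.linalg.norm(pi @ A - pi):
            pi = np.clip(cand, 0.0, None)
            pi /= pi.sum()
    except np.linalg.LinAlgError:
        pass
    if np.linalg.norm(pi @ A - pi) > max(tol, 1e-8):
        raise RuntimeError("stationary distribution did not converge")
    return pi


def emit_state_sequence(A, n_motifs: int, rng: np.random.Generator,
                        *, initial_state: int | None = None, m: int = 3) -> np.ndarray:
    """Sample a state (motif) sequence from the chain.

    The initial state is drawn uniformly over all states unless given; each
    subsequent state follows the source row of ``A``, so every consecutive
    pair is admissible by construction.
    """
    A = validate_matrix(A, m)
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    M = A.shape[0]
    targets = []
    cums = []
    for i in range(M):
        tg = np.flatnonzero(A[i] > 0)
        targets.append([int(v) for v in tg])
        cums.append(np.cumsum(A[i, tg]).tolist())
    out = [0] * n_motifs
    cur = int(rng.integers(M)) if initial_state is None else int(initial_state)
    if not 0 <= cur < M:
        raise ValueError(f"initial_state {cur} out of range")
    out[0] = cur
    if n_motifs > 1:
        u = rng.random(n_motifs - 1).tolist()
        for t in range(1, n_motifs):
            c = cums[cur]
            tg = targets[cur]
            j = bisect_right(c, u[t - 1])
            cur = tg[j if j < len(tg) else len(tg) - 1]
            out[t] = cur
    return np.asarray(out, dtype=np.int64)


def synthesize_amplitudes(states, m: int = 3, rng: np.random.Generator | None = None,
                          *, delta: float = 1.0) -> np.ndarray:
    """Real amplitudes whose sliding-window motif sequence equals ``states``.

    The first window is realised by sorting ``m`` uniform draws into the
    initial motif's order.  Each subsequent sample must fall in the open
    amplitude region that gives the new window the emitted motif: the rank
    of the new sample among the ``m - 1`` carried-over samples is dictated
    by the motif, so the region is an interval between two known amplitudes
    (sampled uniformly) or an unbounded tail (sampled uniformly on a width-
    ``delta`` extension).  The result is tie-free almost surely and the
    motif round trip is exact for any ``delta > 0``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if delta <= 0:
        raise ValueError("delta must be positive")
    states = np.asarray(states, dtype=np.int64)
    if states.ndim != 1 or states.size < 1:
        raise ValueError("states must be a non-empty 1-d sequence")
    alphabet = motif_alphabet(m)
    M = len(alphabet)
    if states.min() < 0 or states.max() >= M:
        raise ValueError("state index out of range")
    adm = admissible_pair_matrix(m)
    ok = adm[states[:-1], states[1:]]
    if not np.all(ok):
        t = int(np.argmin(ok)) + 1
        raise InvalidSequenceError(
            f"forbidden transition {int(states[t - 1])} -> {int(states[t])} at motif index {t}"
        )
    # rank of the newly appended sample (window position m-1) under each motif
    new_rank = [alphabet[s].index(m - 1) for s in range(M)]

    n = states.size + m - 1
    x = [0.0] * n
    first = alphabet[states[0]]
    vals = np.sort(rng.random(m)).tolist()
    for k in range(m):
        x[first[k]] = vals[k]
    if states.size > 1:
        u = rng.random(states.size - 1).tolist()
        st = states.tolist()
        for t in range(1, len(st)):
            known = sorted(x[t : t + m - 1])
            r = new_rank[st[t]]
            if r == 0:
                lo, hi = known[0] - delta, known[0]
            elif r == m - 1:
                lo, hi = known[-1], known[-1] + delta
            else:
                lo, hi = known[r - 1], known[r]
            lam = lo + (hi - lo) * u[t - 1]
            while lam <= lo or lam >= hi:  # guard against landing on a boundary
                lam = lo + (hi - lo) * float(rng.random())
            x[t + m - 1] = lam
    return np.asarray(x)


def generate_series(A, n_samples: int, rng: np.random.Generator, *, m: int = 3,
                    delta: float = 1.0, record_id: str = "series",
                    label: str | None = None,
                    initial_state: int | None = None) -> GeneratedSeries:
    """Generate one synthetic series of length ``n_samples`` from matrix ``A``."""
    if n_samples < m:
        raise ValueError(f"n_samples must be >= m={m}")
    states = emit_state_sequence(A, n_samples - m + 1, rng, initial_state=initial_state, m=m)
    amplitudes = synthesize_amplitudes(states, m, rng, delta=delta)
    return GeneratedSeries(
        record_id=record_id,
        label=label,
        amplitudes=amplitudes,
        states=states,
        initial_state=int(states[0]),
        m=m,
    )


def generate_dataset(triple_a, triple_b, n_per_class: int, n_samples: int,
                     rng: np.random.Generator, *, m: int = 3, delta: float = 1.0,
                     labels: tuple[str, str] = ("A", "B")) -> list[GeneratedSeries]:
    """Two labelled classes of synthetic series, one shared triple per class.

    Each series draws from its own RNG substream spawned from ``rng``, so a
    dataset is reproducible and the series are independent.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    mats = (build_matrix_from_triple(triple_a, m), build_matrix_from_triple(triple_b, m))
    streams = rng.spawn(2 * n_per_class)
    out: list[GeneratedSeries] = []
    k = 0
    for cls, (label, A) in enumerate(zip(labels, mats)):
        for i in range(n_per_class):
            out.append(
                generate_series(
                    A, n_samples, streams[k], m=m, delta=delta,
                    record_id=f"{label}{i:03d}", label=label,
                )
            )
            k += 1
    return out
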