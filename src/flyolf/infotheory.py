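"""Mutual information between odor identity and the Kenyon-cell population state.

The mushroom-body readout on each trial is a binary KC vector, encoded as an
integer in ``[0, 2**n_kc)``.  With K equiprobable odors and T trials per
odor the plug-in estimator is

    MI = sum_{n,k} p(n,k) * log2( p(n,k) / (p(n) p(k)) )

over the empirical joint distribution.  Because the plug-in estimate is
biased upward at finite T, the estimator of record here is quadratic
extrapolation: MI is recomputed on disjoint halves and quarters of the
trials, the three points are fitted exactly with

    MI(N) = MI_inf + a/N + b/N**2

and ``MI_inf`` is reported as the bias-corrected value.  States are stored
sparsely (only observed codes); unobserved states contribute nothing to the
sum, and the conventional ``p(n) = 1e-8`` substitution for never-observed
states is applied literally but is numerically inert under the
``0 * log 0 = 0`` convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .environment import ParameterError

__all__ = [
    "TrialRecord",
    "JointCounts",
    "MIEstimate",
    "encode_state",
    "encode_states",
    "decode_state",
    "tabulate",
    "plugin_mi",
    "mi_from_codes",
    "extrapolate_quadratic",
    "quadratic_extrapolation",
]

logger = logging.getLogger(__name__)

#: Substituted marginal probability for states that never occur.
UNSEEN_STATE_PROB = 1e-8

_warned_negative_mi = False


class TrialRecord(NamedTuple):
    """One (odor, response) observation: the unit of MI estimation."""

    odor_index: int
    state_code: int


@dataclass(frozen=True, eq=False)
class JointCounts:
    """Sparse contingency table of (odor, KC-state) observations.

    ``counts[k, j]`` is the number of trials in which odor ``k`` evoked the
    state with code ``state_codes[j]``.  Only observed codes are stored;
    the table is mathematically equivalent to the dense K x 2**n_kc table
    because absent states have zero counts.
    """

    counts: np.ndarray
    state_codes: np.ndarray
    n_odors: int
    n_states: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        codes = np.asarray(self.state_codes, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != self.n_odors or c.shape[1] != codes.size:
            raise ParameterError("counts must be (n_odors, n_observed_states)")
        if (c < 0).any():
            raise ParameterError("counts must be non-negative")
        if codes.size and (codes.min() < 0 or codes.max() >= self.n_states):
            raise ParameterError("state codes out of range")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "state_codes", codes)

    @property
    def trials_per_odor(self) -> int | None:
        """Common row total, or None if the rows are unbalanced."""
        row = self.counts.sum(axis=1)
        if row.size and (row == row[0]).all():
            return int(row[0])
        return None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MIEstimate:
    """Plug-in and bias-corrected MI plus the fitted 1/N expansion coefficients."""

    mi_uncorrected: float
    mi_corrected: float
    coeff_a: float
    coeff_b: float


def encode_state(active) -> int:
    """Bijectively encode a binary KC vector: cell ``i`` contributes ``2**i``."""
    a = np.asarray(getattr(active, "active", active), dtype=np.int64)
    return int(a @ (np.int64(1) << np.arange(a.size, dtype=np.int64)))


def encode_states(active_matrix: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_state` over rows of a (trials, n_kc) matrix."""
    m = np.asarray(active_matrix, dtype=np.int64)
    return m @ (np.int64(1) << np.arange(m.shape[1], dtype=np.int64))


def decode_state(code: int, n_kc: int) -> np.ndarray:
    """Inverse of :func:`encode_state`: recover the binary KC vector."""
    if not (0 <= code < 2**n_kc):
        raise ParameterError(f"code {code} out of range for {n_kc} cells")
    return (code >> np.arange(n_kc, dtype=np.int64)) & 1


def tabulate(
    trials: Sequence[TrialRecord],
    n_odors: int,
    n_states: int,
) -> JointCounts:
    """Build the exact contingency table from raw trial records."""
    if n_odors < 1 or n_states < 1:
        raise ParameterError("n_odors and n_states must be >= 1")
    ks = np.asarray([t[0] for t in trials], dtype=np.int64)
    ns = np.asarray([t[1] for t in trials], dtype=np.int64)
    if ks.size:
        if ks.min() < 0 or ks.max() >= n_odors:
            raise ParameterError("odor index out of range")
        if ns.min() < 0 or ns.max() >= n_states:
            raise ParameterError("state code out of range")
    codes, inv = np.unique(ns, return_inverse=True)
    counts = np.zeros((n_odors, codes.size), dtype=np.int64)
    np.add.at(counts, (ks, inv), 1)
    return JointCounts(
        counts=counts, state_codes=codes, n_odors=n_odors, n_states=n_states
    )


def _mi_from_counts(counts: np.ndarray, base: float) -> float:
    """Plug-in MI (in log-``base`` units) of a non-negative count table."""
    total = counts.sum()
    if total <= 0:
        raise ParameterError("cannot estimate MI from an empty table")
    pnk = counts / total
    pk = pnk.sum(axis=1, keepdims=True)
    pn = pnk.sum(axis=0, keepdims=True)
    # Unobserved states get the conventional 1e-8 marginal; their joint mass
    # is zero so they still contribute nothing.
    pn = np.where(pn == 0.0, UNSEEN_STATE_PROB, pn)
    mask = pnk > 0
    ratio = pnk[mask] / (pk * pn + (~mask))[mask]
    return float((pnk[mask] * np.log(ratio)).sum() / math.log(base))


def plugin_mi(joint: JointCounts, base: float = 2.0) -> float:
    """Plug-in mutual information of a contingency table, in bits by default."""
    return _mi_from_counts(joint.counts, base)


def mi_from_codes(
    codes_by_odor: Sequence[np.ndarray],
    base: float = 2.0,
) -> float:
    """Plug-in MI directly from per-odor arrays of encoded KC states."""
    uniq, inv_by_odor = _compact(codes_by_odor)
    counts = np.stack(
        [np.bincount(inv, minlength=uniq.size) for inv in inv_by_odor]
    )
    return _mi_from_counts(counts, base)


def _compact(codes_by_odor: Sequence[np.ndarray]):
    """Relabel state codes to a dense 0..U-1 alphabet shared across odors."""
    arrays = [np.asarray(c, dtype=np.int64).ravel() for c in codes_by_odor]
    lengths = [a.size for a in arrays]
    uniq, inv = np.unique(np.concatenate(arrays), return_inverse=True)
    splits = np.split(inv, np.cumsum(lengths)[:-1])
    return uniq, splits


def extrapolate_quadratic(
    n: int,
    mi_full: float,
    mi_half: float,
    mi_quarter: float,
) -> tuple[float, float, float]:
    """Exactly solve ``MI(N') = MI_inf + a/N' + b/N'**2`` from three points.

    The three plug-in estimates at N' = ``n``, ``n/2`` and ``n/4`` determine
    the expansion uniquely (the design matrix in 1/N' is Vandermonde with
    distinct nodes).  Returns ``(mi_inf, a, b)``; subtracting ``a/n + b/n**2``
    from ``mi_full`` gives the same ``mi_inf`` algebraically.
    """
    design = np.array(
        [
            [1.0, 1.0 / n, 1.0 / n**2],
            [1.0, 2.0 / n, 4.0 / n**2],
            [1.0, 4.0 / n, 16.0 / n**2],
        ]
    )
    mi_inf, coeff_a, coeff_b = np.linalg.solve(
        design, np.array([mi_full, mi_half, mi_quarter], dtype=float)
    )
    return float(mi_inf), float(coeff_a), float(coeff_b)


def quadratic_extrapolation(
    trials_by_odor: Sequence[np.ndarray] | Sequence[Sequence[TrialRecord]],
    n_states: int | None = None,
    rng: np.random.Generator | None = None,
    base: float = 2.0,
) -> MIEstimate:
    """Bias-corrected MI by exact quadratic extrapolation in 1/N.

    Parameters
    ----------
    trials_by_odor
        One sequence per odor, each of the same length N (divisible by 4,
        N >= 8), holding encoded KC states (or TrialRecords, whose codes are
        used).  Stratifying by odor keeps the odors equiprobable in every
        subsample.
    n_states
        Size of the full state alphabet; only used for validation.
    rng
        Source of the random disjoint half/quarter partitions, drawn once.

    The plug-in MI is evaluated on the full data, averaged over the 2
    disjoint halves, and averaged over the 4 disjoint quarters; the three
    points determine ``MI_inf + a/N + b/N**2`` exactly and ``MI_inf`` is
    returned as ``mi_corrected`` (floored at zero: truly negative
    information is an extrapolation artifact).
    """
    global _warned_negative_mi
    arrays = []
    for odor_trials in trials_by_odor:
        if isinstance(odor_trials, np.ndarray):
            arr = odor_trials.astype(np.int64).ravel()
        else:
            seq = list(odor_trials)
            if seq and isinstance(seq[0], tuple):
                arr = np.asarray([t[1] for t in seq], dtype=np.int64)
            else:
                arr = np.asarray(seq, dtype=np.int64)
        arrays.append(arr)
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ParameterError("all odors must have the same number of trials")
    n = sizes.pop()
    if n < 8:
        raise ParameterError(f"need >= 8 trials per odor, got {n}")
    if n % 4:
        raise ParameterError(f"trials per odor must be divisible by 4, got {n}")
    if n_states is not None:
        for a in arrays:
            if a.size and (a.min() < 0 or a.max() >= n_states):
                raise ParameterError("state code out of range")
    if rng is None:
        rng = np.random.default_rng()

    uniq, inv_by_odor = _compact(arrays)
    u = uniq.size
    perms = [rng.permutation(n) for _ in arrays]

    def mi_of(selector: slice | None) -> float:
        counts = np.stack(
            [
                np.bincount(inv if selector is None else inv[perm[selector]],
                            minlength=u)
                for inv, perm in zip(inv_by_odor, perms)
            ]
        )
        return _mi_from_counts(counts, base)

    mi_full = mi_of(None)
    half = n // 2
    quarter = n // 4
    mi_half = np.mean([mi_of(slice(i * half, (i + 1) * half)) for i in range(2)])
    mi_quarter = np.mean(
        [mi_of(slice(i * quarter, (i + 1) * quarter)) for i in range(4)]
    )

    mi_inf, coeff_a, coeff_b = extrapolate_quadratic(
        n, mi_full, float(mi_half), float(mi_quarter)
    )
    corrected = mi_inf
    if corrected < 0.0:
        level = logging.DEBUG if _warned_negative_mi else logging.WARNING
        logger.log(
            level,
            "extrapolated MI %.3g < 0; reporting 0 (further floors logged at DEBUG)",
            corrected,
        )
        _warned_negative_mi = True
        corrected = 0.0
    return MIEstimate(
        mi_uncorrected=float(mi_full),
        mi_corrected=corrected,
        coeff_a=float(coeff_a),
        coeff_b=float(coeff_b),
    )
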