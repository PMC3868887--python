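"""Feed-forward olfactory circuit: OPN activation, random connectome, KC thresholding, inhibition.

The circuit has two stages.  Stage one (antenna + antennal lobe collapsed):
each OPN reached by the presented odor fires independently with probability
``1 - exp(-beta * c)``, so low concentrations activate few and high
concentrations nearly all reached OPNs.  Stage two (mushroom body): each
Kenyon cell (KC) sums its binary synaptic inputs through a Bernoulli(r)
connectome and fires iff the sum strictly exceeds its threshold.  Optional
activity-dependent feedback inhibition deletes each KC spike independently
with probability ``exp(-alpha * chi)``, where ``chi`` is the pre-inhibition
KC activity of the trial; larger ``alpha`` means weaker inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import Odor, ParameterError

__all__ = [
    "Connectome",
    "ALState",
    "KCState",
    "activation_probability",
    "sample_connectome",
    "sample_al_state",
    "kc_response",
    "inhibition_probability",
    "apply_inhibition",
    "simulate_trial",
]


@dataclass(frozen=True, eq=False)
class Connectome:
    """One "fly": a binary OPN-to-KC connection matrix.

    ``weights`` has shape ``(n_kc, n_glomeruli)``; entry ``(i, j)`` is 1 iff
    OPN ``j`` synapses onto KC ``i``.
    """

    weights: np.ndarray
    connectivity_rate: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2:
            raise ParameterError("connectome weights must be a 2-D matrix")
        if not np.isin(w, (0, 1)).all():
            raise ParameterError("connectome weights must be binary")
        if not (0.0 < self.connectivity_rate < 1.0):
            raise ParameterError(
                f"connectivity rate must lie in (0, 1), got {self.connectivity_rate!r}"
            )
        object.__setattr__(self, "weights", w.astype(np.uint8))

    @property
    def n_kc(self) -> int:
        return self.weights.shape[0]

    @property
    def n_glomeruli(self) -> int:
        return self.weights.shape[1]

    def to_csv(self, path) -> None:
        """Dense 0/1 CSV, one row per Kenyon cell; rate kept in a comment."""
        np.savetxt(
            path,
            self.weights,
            fmt="%d",
            delimiter=",",
            header=f"connectivity_rate: {self.connectivity_rate!r}",
        )

    @classmethod
    def from_csv(cls, path) -> "Connectome":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        rate = float(first.lstrip("# ").partition(":")[2])
        weights = np.loadtxt(path, delimiter=",", dtype=np.uint8, ndmin=2)
        return cls(weights=weights, connectivity_rate=rate)


@dataclass(frozen=True, eq=False)
class ALState:
    """Binary antennal-lobe state: which OPNs fired in one trial."""

    active: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.active)
        if a.ndim != 1 or not np.isin(a, (0, 1)).all():
            raise ParameterError("AL state must be a binary vector")
        object.__setattr__(self, "active", a.astype(np.uint8))

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


@dataclass(frozen=True, eq=False)
class KCState:
    """Binary mushroom-body state: which Kenyon cells fired in one trial."""

    active: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.active)
        if a.ndim != 1 or not np.isin(a, (0, 1)).all():
            raise ParameterError("KC state must be a binary vector")
        object.__setattr__(self, "active", a.astype(np.uint8))

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def activation_probability(concentration: float, beta: float) -> float:
    """Probability that a reached OPN fires: ``1 - exp(-beta * c)``.

    Strictly increasing in both arguments; 0 at zero concentration and
    saturating toward 1 as ``beta * c`` grows.
    """
    if concentration < 0:
        raise ParameterError(f"concentration must be >= 0, got {concentration!r}")
    if not (beta > 0):
        raise ParameterError(f"beta must be positive, got {beta!r}")
    return -math.expm1(-beta * concentration)


def sample_connectome(
    n_kc: int,
    n_glomeruli: int,
    r: float,
    rng: np.random.Generator,
) -> Connectome:
    """Draw a Bernoulli(r) connectome: each OPN->KC synapse exists independently."""
    if n_kc < 1 or n_glomeruli < 1:
        raise ParameterError("n_kc and n_glomeruli must be >= 1")
    if not (0.0 < r < 1.0):
        raise ParameterError(f"connectivity rate must lie in (0, 1), got {r!r}")
    weights = (rng.random((n_kc, n_glomeruli)) < r).astype(np.uint8)
    return Connectome(weights=weights, connectivity_rate=r)


def sample_al_state(
    odor: Odor,
    n_glomeruli: int,
    beta: float,
    rng: np.random.Generator,
) -> ALState:
    """Sample one trial's antennal-lobe state for ``odor``.

    Each reachable OPN fires independently with
    :func:`activation_probability`; unreached OPNs stay silent.
    """
    p = activation_probability(odor.concentration, beta)
    active = np.zeros(n_glomeruli, dtype=np.uint8)
    reach = np.asarray(odor.reachable_opns, dtype=np.intp)
    active[reach] = rng.random(reach.size) < p
    return ALState(active=active)


def kc_response(connectome: Connectome, al: ALState, theta: int) -> KCState:
    """Deterministic KC thresholding: cell ``i`` fires iff its summed input > theta.

    The comparison is strict, so a cell receiving exactly ``theta`` active
    inputs stays silent.
    """
    if theta < 1:
        raise ParameterError(f"theta must be >= 1, got {theta!r}")
    if al.active.shape[0] != connectome.n_glomeruli:
        raise ParameterError(
            f"AL state has {al.active.shape[0]} OPNs but connectome expects "
            f"{connectome.n_glomeruli}"
        )
    syn = connectome.weights.astype(np.int64) @ al.active.astype(np.int64)
    return KCState(active=(syn > theta).astype(np.uint8))


def inhibition_probability(
    n_active_kc: int,
    alpha: float,
    *,
    n_kc: int | None = None,
    activity: str = "count",
) -> float:
    """Per-spike feedback-inhibition probability ``exp(-alpha * chi)``.

    ``chi`` is the pre-inhibition mushroom-body activity of the trial: the
    count of active KCs by default, or the active fraction when
    ``activity="fraction"`` (requires ``n_kc``).  The probability decreases
    with activity and with ``alpha``; with no spikes it is vacuously 1.
    """
    if n_active_kc < 0:
        raise ParameterError("n_active_kc must be >= 0")
    if not (alpha > 0):
        raise ParameterError(f"alpha must be positive, got {alpha!r}")
    if activity == "count":
        chi = float(n_active_kc)
    elif activity == "fraction":
        if n_kc is None or n_kc < 1:
            raise ParameterError("fraction activity needs the KC population size")
        chi = n_active_kc / n_kc
    else:
        raise ParameterError(f"unknown activity convention {activity!r}")
    return math.exp(-alpha * chi)


def apply_inhibition(
    kc: KCState,
    alpha: float,
    rng: np.random.Generator,
    *,
    activity: str = "count",
) -> KCState:
    """Delete each KC spike independently with the trial's inhibition probability.

    The probability is computed once from the pre-inhibition state and then
    applied in a single simultaneous pass; silent cells are unaffected.  The
    returned state is the final mushroom-body output.
    """
    p_i = inhibition_probability(
        kc.n_active, alpha, n_kc=kc.active.shape[0], activity=activity
    )
    out = kc.active.copy()
    spikes = np.flatnonzero(out)
    if spikes.size:
        out[spikes[rng.random(spikes.size) < p_i]] = 0
    return KCState(active=out)


def simulate_trial(
    odor: Odor,
    connectome: Connectome,
    theta: int,
    beta: float,
    alpha: float | None,
    rng: np.random.Generator,
    *,
    activity: str = "count",
) -> KCState:
    """One full stimulus presentation: AL sampling, KC thresholding, inhibition.

    With ``alpha=None`` the inhibition stage is skipped (the purely
    feed-forward condition).
    """
    al = sample_al_state(odor, connectome.n_glomeruli, beta, rng)
    kc = kc_response(connectome, al, theta)
    if alpha is not None:
        kc = apply_inhibition(kc, alpha, rng, activity=activity)
    return kc
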