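"""Synthetic odor environments for the fly olfactory circuit model.

An odor is treated as an abstract stimulus: the subset of antennal-lobe
glomeruli (one olfactory projection neuron, OPN, per glomerulus) that the
odor's chemical components can reach, together with a scalar concentration
in ``(0, 1]``.  Because natural odors are blends of many compounds, the
number of reachable OPNs per odor is drawn from a Gaussian with mean 35 and
variance 8 over a universe of 50 glomeruli, rounded to the nearest integer
and clamped to ``[1, n_glomeruli]``.  Which OPNs are reachable is a uniform
random subset of that size.

All odors in one panel share a single concentration; within an experiment
the panel plays the role of the "environment" whose identity the mushroom
body must encode.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DEFAULT_N_GLOMERULI",
    "DEFAULT_MU_OPN",
    "DEFAULT_SIGMA2_OPN",
    "Odor",
    "OdorPanel",
    "draw_reached_count",
    "draw_odor_panel",
]

#: Number of antennal-lobe glomeruli (= model OPNs) in the adult fly.
DEFAULT_N_GLOMERULI = 50
#: Mean number of OPNs reached by an odor.
DEFAULT_MU_OPN = 35.0
#: Variance (not sd) of the reached-OPN count.
DEFAULT_SIGMA2_OPN = 8.0


class ParameterError(ValueError):
    """Raised when a model parameter is outside its admissible range."""


@dataclass(frozen=True)
class Odor:
    """One environmental stimulus.

    Parameters
    ----------
    index
        Integer label ``k`` of the odor within its panel.
    reachable_opns
        Strictly increasing tuple of OPN indices this odor can activate.
    concentration
        Shared scalar concentration ``c`` in ``(0, 1]``.
    """

    index: int
    reachable_opns: tuple[int, ...]
    concentration: float

    def __post_init__(self) -> None:
        opns = tuple(sorted(int(j) for j in self.reachable_opns))
        if len(opns) == 0:
            raise ParameterError("an odor must reach at least one OPN")
        if len(set(opns)) != len(opns):
            raise ParameterError("reachable OPN indices must be unique")
        if any(j < 0 for j in opns):
            raise ParameterError("OPN indices must be non-negative")
        if not (0.0 < self.concentration <= 1.0):
            raise ParameterError(
                f"concentration must lie in (0, 1], got {self.concentration!r}"
            )
        object.__setattr__(self, "reachable_opns", opns)

    @property
    def n_reachable(self) -> int:
        """Number of OPNs this odor can activate."""
        return len(self.reachable_opns)


@dataclass(frozen=True)
class OdorPanel:
    """An ordered collection of equiprobable odors over one glomerular universe."""

    odors: tuple[Odor, ...]
    n_glomeruli: int = DEFAULT_N_GLOMERULI

    def __post_init__(self) -> None:
        odors = tuple(self.odors)
        if len(odors) == 0:
            raise ParameterError("a panel needs at least one odor")
        if self.n_glomeruli < 1:
            raise ParameterError("n_glomeruli must be >= 1")
        for k, odor in enumerate(odors):
            if odor.index != k:
                raise ParameterError(
                    f"odor indices must be 0..{len(odors) - 1} in order; "
                    f"got {odor.index} at position {k}"
                )
            if odor.reachable_opns[-1] >= self.n_glomeruli:
                raise ParameterError(
                    f"odor {k} reaches OPN {odor.reachable_opns[-1]} outside "
                    f"the {self.n_glomeruli}-glomerulus universe"
                )
        object.__setattr__(self, "odors", odors)

    def __len__(self) -> int:
        return len(self.odors)

    def __iter__(self) -> Iterator[Odor]:
        return iter(self.odors)

    def __getitem__(self, k: int) -> Odor:
        return self.odors[k]

    def to_csv(self, path) -> None:
        """Write the panel as UTF-8 CSV, one row per odor.

        The glomerular universe size is kept in a leading ``#`` comment so a
        panel file is self-contained.
        """
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# n_glomeruli: {self.n_glomeruli}\n")
            writer = csv.writer(fh)
            writer.writerow(["index", "concentration", "reachable_opns"])
            for odor in self.odors:
                writer.writerow(
                    [
                        odor.index,
                        repr(odor.concentration),
                        ",".join(str(j) for j in odor.reachable_opns),
                    ]
                )

    @classmethod
    def from_csv(cls, path) -> "OdorPanel":
        """Read a panel written by :meth:`to_csv` (exact round trip)."""
        n_glomeruli = DEFAULT_N_GLOMERULI
        with open(path, newline="", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                key, _, value = first.lstrip("# ").partition(":")
                if key.strip() == "n_glomeruli":
                    n_glomeruli = int(value)
            else:
                fh.seek(0)
            reader = csv.DictReader(fh)
            odors = [
                Odor(
                    index=int(row["index"]),
                    reachable_opns=tuple(
                        int(tok) for tok in row["reachable_opns"].split(",")
                    ),
                    concentration=float(row["concentration"]),
                )
                for row in reader
            ]
        return cls(odors=tuple(odors), n_glomeruli=n_glomeruli)


def draw_reached_count(
    mu: float,
    sigma2: float,
    n_glomeruli: int,
    rng: np.random.Generator,
) -> int:
    """Draw the number of OPNs an odor reaches.

    A single Gaussian variate with mean ``mu`` and *variance* ``sigma2`` is
    rounded to the nearest integer and clamped to ``[1, n_glomeruli]``:
    every odor must remain detectable and cannot reach more glomeruli than
    exist.  At the default (35, 8) the clamp is essentially never active.
    """
    if not (mu > 0):
        raise ParameterError(f"mu must be positive, got {mu!r}")
    if not (sigma2 > 0):
        raise ParameterError(f"sigma2 must be positive, got {sigma2!r}")
    if n_glomeruli < 1:
        raise ParameterError("n_glomeruli must be >= 1")
    value = int(round(rng.normal(mu, math.sqrt(sigma2))))
    return min(max(value, 1), n_glomeruli)


def draw_odor_panel(
    n_odors: int,
    concentration: float,
    mu: float = DEFAULT_MU_OPN,
    sigma2: float = DEFAULT_SIGMA2_OPN,
    n_glomeruli: int = DEFAULT_N_GLOMERULI,
    rng: np.random.Generator | None = None,
) -> OdorPanel:
    """Draw a panel of ``n_odors`` equiprobable odors at one concentration.

    Each odor's reachable set is a uniform random subset of the glomeruli,
    of size :func:`draw_reached_count`.  With a fixed generator the panel is
    fully reproducible.
    """
    if n_odors < 1:
        raise ParameterError("n_odors must be >= 1")
    if not (0.0 < concentration <= 1.0):
        raise ParameterError(
            f"concentration must lie in (0, 1], got {concentration!r}"
        )
    if rng is None:
        rng = np.random.default_rng()
    odors = []
    for k in range(n_odors):
        size = draw_reached_count(mu, sigma2, n_glomeruli, rng)
        subset = rng.choice(n_glomeruli, size=size, replace=False)
        odors.append(
            Odor(
                index=k,
                reachable_opns=tuple(int(j) for j in subset),
                concentration=concentration,
            )
        )
    return OdorPanel(odors=tuple(odors), n_glomeruli=n_glomeruli)
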