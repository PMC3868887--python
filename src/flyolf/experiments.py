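"""Parameter-sweep protocol: fly replicates, grids over (r, theta, alpha, c), tidy results.

One "experiment" follows the study protocol: for each replicate fly a fresh
Bernoulli(r) connectome is drawn, every odor of a panel is presented for
``n_trials`` trials, the evoked KC states are encoded, and the
bias-corrected mutual information between odor identity and KC state is
estimated by quadratic extrapolation.  MI is then averaged (mean +/- sd)
across flies for every grid point of the requested parameter sweep.

Randomness is organised so that a single master seed fixes everything and
the result is independent of how work is scheduled: every consumer derives
its stream from a ``numpy`` SeedSequence whose entropy is the tuple
``(master_seed, r_index, c_index, fly_index)`` plus a fixed ``spawn_key``
tag -- (1,) connectome, (2,) trial noise, (3, t, a) inhibition and
(4, t, a) partition for the t-th threshold and a-th alpha of the grid.
Odor panels use the tag entropy ``(master_seed, 161, c_index[, fly_index])``
so the same flies smell the same odors at every connectivity rate.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import sample_connectome, Connectome
from .environment import (
    DEFAULT_MU_OPN,
    DEFAULT_N_GLOMERULI,
    DEFAULT_SIGMA2_OPN,
    OdorPanel,
    ParameterError,
    draw_odor_panel,
)
from .infotheory import encode_states, quadratic_extrapolation
from .circuit import activation_probability

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "run_fly",
    "sweep",
    "argmax_threshold",
    "argmax_connectivity",
    "mean_over_thresholds",
    "write_results",
    "read_results",
    "render_heatmap",
    "DEFAULT_R_GRID",
    "FIG6_ALPHA_GRID",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_CONCENTRATION_GRID",
]

logger = logging.getLogger(__name__)

_PANEL_TAG = 161  # entropy tag separating panel streams from fly streams

#: Connectivity grid for full (r, theta) surfaces.
DEFAULT_R_GRID = tuple(round(0.05 * i, 2) for i in range(1, 20))
#: The six inhibition strengths reported per-panel in the study.
FIG6_ALPHA_GRID = (0.1, 0.4, 0.7, 0.9, 1.3, 1.7)
#: Fig-6 grid plus the stated endpoints of the admissible alpha range.
DEFAULT_ALPHA_GRID = (0.05,) + FIG6_ALPHA_GRID + (1.75,)
#: Concentration grid for concentration-sweep curves.
DEFAULT_CONCENTRATION_GRID = (0.05, 0.15, 0.30, 0.45, 0.60, 0.75, 0.90)

GridF = float | Sequence[float]


def _as_tuple(value, cast) -> tuple:
    if value is None:
        return (None,)
    if np.isscalar(value):
        return (cast(value),)
    return tuple(None if v is None else cast(v) for v in value)


@dataclass(eq=True)
class ExperimentConfig:
    """Full description of one sweep; scalar fields may also be grids.

    ``alpha=None`` (or None inside the alpha grid) is the no-inhibition
    condition.  ``n_trials`` must be divisible by 4 for the quadratic
    extrapolation partitions.

    ``inhibition_activity`` selects what the inhibition exponent multiplies:
    the active *fraction* of KCs (default; the mean activity per cell, which
    keeps ``alpha`` comparable across KC population sizes and places the
    optimum at moderate ``alpha``) or the raw active *count*.
    """

    n_kc: int = 10
    n_glomeruli: int = DEFAULT_N_GLOMERULI
    n_odors: int = 5
    n_trials: int = 100
    n_flies: int = 20
    beta: float = 1.32
    mu_opn: float = DEFAULT_MU_OPN
    sigma2_opn: float = DEFAULT_SIGMA2_OPN
    concentration: GridF = 0.15
    theta: int | Sequence[int] = tuple(range(1, 21))
    r: GridF = 0.3
    alpha: float | None | Sequence[float | None] = None
    seed: int = 0
    inhibition_activity: str = "fraction"
    log_base: float = 2.0
    shared_panel: bool = False

    def __post_init__(self) -> None:
        self.theta = _as_tuple(self.theta, int)
        self.r = _as_tuple(self.r, float)
        self.concentration = _as_tuple(self.concentration, float)
        self.alpha = _as_tuple(self.alpha, float)
        self.validate()

    def validate(self) -> None:
        if self.n_kc < 1 or self.n_glomeruli < 1 or self.n_odors < 1:
            raise ParameterError("population sizes must be >= 1")
        if self.n_trials < 8 or self.n_trials % 4:
            raise ParameterError("n_trials must be >= 8 and divisible by 4")
        if self.n_flies < 1:
            raise ParameterError("n_flies must be >= 1")
        if self.inhibition_activity not in ("count", "fraction"):
            raise ParameterError("inhibition_activity must be 'count' or 'fraction'")
        if self.log_base <= 1.0:
            raise ParameterError("log_base must exceed 1")
        for t in self.theta:
            if t < 1:
                raise ParameterError("theta values must be >= 1")
        for r in self.r:
            if not (0.0 < r < 1.0):
                raise ParameterError("r values must lie in (0, 1)")
        for c in self.concentration:
            if not (0.0 < c <= 1.0):
                raise ParameterError("concentrations must lie in (0, 1]")
        for a in self.alpha:
            if a is not None and a <= 0:
                raise ParameterError("alpha values must be positive (or None)")

    # -- plain-text config file ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("theta", "r", "concentration", "alpha"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Tidy sweep table: one row per (r, concentration, theta, alpha) point."""

    table: pd.DataFrame
    config: ExperimentConfig


# -- simulation core ---------------------------------------------------------


def _fly_mi_table(
    panel: OdorPanel,
    connectome: Connectome,
    *,
    thetas: Sequence[int],
    alphas: Sequence[float | None],
    n_trials: int,
    beta: float,
    inhibition_activity: str,
    log_base: float,
    fly_entropy: Sequence[int],
) -> np.ndarray:
    """Corrected MI for one fly at every (theta, alpha) grid point.

    The trial noise (which reached OPNs fire) is sampled once per fly and
    reused across thresholds and inhibition strengths, exactly as a real
    presentation would be read out at different parameter settings; only
    the inhibition deletions and the extrapolation partitions get their own
    per-(theta, alpha) streams.
    """
    entropy = list(int(e) for e in fly_entropy)
    w = connectome.weights.astype(np.int64)
    n_kc = connectome.n_kc
    al_rng = np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(2,)))

    syn_by_odor = []
    for odor in panel:
        p = activation_probability(odor.concentration, beta)
        reach = np.asarray(odor.reachable_opns, dtype=np.intp)
        fired = al_rng.random((n_trials, reach.size)) < p
        syn_by_odor.append(fired.astype(np.int64) @ w[:, reach].T)

    out = np.empty((len(thetas), len(alphas)))
    for ti, theta in enumerate(thetas):
        pre = [s > theta for s in syn_by_odor]
        chi = [p_k.sum(axis=1) for p_k in pre]
        for ai, alpha in enumerate(alphas):
            if alpha is None:
                codes = [encode_states(p_k) for p_k in pre]
            else:
                inh_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy, spawn_key=(3, ti, ai))
                )
                codes = []
                for p_k, chi_k in zip(pre, chi):
                    chi_eff = chi_k if inhibition_activity == "count" else chi_k / n_kc
                    p_i = np.exp(-alpha * chi_eff)
                    keep = inh_rng.random(p_k.shape) >= p_i[:, None]
                    codes.append(encode_states(p_k & keep))
            part_rng = np.random.default_rng(
                np.random.SeedSequence(entropy, spawn_key=(4, ti, ai))
            )
            est = quadratic_extrapolation(
                codes, n_states=2**n_kc, rng=part_rng, base=log_base
            )
            out[ti, ai] = est.mi_corrected
    return out


def run_fly(
    config: ExperimentConfig,
    panel: OdorPanel,
    fly_seed,
) -> float:
    """Corrected MI (bits) of a single fly at a scalar parameter point.

    ``fly_seed`` may be an int or a ``numpy.random.SeedSequence``; the same
    seed and panel always reproduce the same estimate.
    """
    for name in ("theta", "r", "concentration", "alpha"):
        if len(getattr(config, name)) != 1:
            raise ParameterError(f"run_fly needs a scalar {name}")
    if isinstance(fly_seed, np.random.SeedSequence):
        entropy = list(np.atleast_1d(fly_seed.entropy))
    else:
        entropy = [int(fly_seed)]
    conn_rng = np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(1,)))
    connectome = sample_connectome(
        config.n_kc, config.n_glomeruli, config.r[0], conn_rng
    )
    table = _fly_mi_table(
        panel,
        connectome,
        thetas=config.theta,
        alphas=config.alpha,
        n_trials=config.n_trials,
        beta=config.beta,
        inhibition_activity=config.inhibition_activity,
        log_base=config.log_base,
        fly_entropy=entropy,
    )
    return float(table[0, 0])


def _panel_entropy(config: ExperimentConfig, c_idx: int, fly: int) -> list[int]:
    entropy = [int(config.seed), _PANEL_TAG, c_idx]
    if not config.shared_panel:
        entropy.append(fly)
    return entropy


def _sweep_task(config: ExperimentConfig, c_idx: int, r_idx: int, fly: int) -> np.ndarray:
    panel = draw_odor_panel(
        config.n_odors,
        config.concentration[c_idx],
        mu=config.mu_opn,
        sigma2=config.sigma2_opn,
        n_glomeruli=config.n_glomeruli,
        rng=np.random.default_rng(
            np.random.SeedSequence(_panel_entropy(config, c_idx, fly))
        ),
    )
    entropy = [int(config.seed), r_idx, c_idx, fly]
    conn_rng = np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(1,)))
    connectome = sample_connectome(
        config.n_kc, config.n_glomeruli, config.r[r_idx], conn_rng
    )
    return _fly_mi_table(
        panel,
        connectome,
        thetas=config.theta,
        alphas=config.alpha,
        n_trials=config.n_trials,
        beta=config.beta,
        inhibition_activity=config.inhibition_activity,
        log_base=config.log_base,
        fly_entropy=entropy,
    )


def sweep(config: ExperimentConfig, jobs: int = 1) -> SweepResult:
    """Run the full Cartesian sweep and average corrected MI across flies.

    With ``jobs > 1`` the (concentration, r, fly) tasks run in parallel via
    joblib; the per-task seed scheme makes the result identical for any
    worker count.
    """
    tasks = list(
        itertools.product(
            range(len(config.concentration)),
            range(len(config.r)),
            range(config.n_flies),
        )
    )
    if jobs != 1:
        from joblib import Parallel, delayed

        tables = Parallel(n_jobs=jobs)(
            delayed(_sweep_task)(config, ci, ri, f) for ci, ri, f in tasks
        )
    else:
        tables = [_sweep_task(config, ci, ri, f) for ci, ri, f in tasks]

    shape = (
        len(config.concentration),
        len(config.r),
        config.n_flies,
        len(config.theta),
        len(config.alpha),
    )
    cube = np.empty(shape)
    for (ci, ri, f), table in zip(tasks, tables):
        cube[ci, ri, f] = table
    mean = cube.mean(axis=2)
    sd = cube.std(axis=2, ddof=1) if config.n_flies > 1 else np.zeros_like(mean)

    rows = []
    for ci, c in enumerate(config.concentration):
        for ri, r in enumerate(config.r):
            for ti, theta in enumerate(config.theta):
                for ai, alpha in enumerate(config.alpha):
                    rows.append(
                        {
                            "n_kc": config.n_kc,
                            "r": r,
                            "concentration": c,
                            "theta": theta,
                            "alpha": np.nan if alpha is None else alpha,
                            "mi_mean": mean[ci, ri, ti, ai],
                            "mi_sd": sd[ci, ri, ti, ai],
                            "n_flies": config.n_flies,
                        }
                    )
    return SweepResult(table=pd.DataFrame(rows), config=config)


# -- read-outs ---------------------------------------------------------------


def _filter(table: pd.DataFrame, fixed: Mapping | None) -> pd.DataFrame:
    df = table
    for key, value in (fixed or {}).items():
        if key == "alpha" and (value is None or (np.isscalar(value) and pd.isna(value))):
            df = df[df["alpha"].isna()]
        else:
            df = df[np.isclose(df[key], value)]
    return df


def _argmax_along(result: SweepResult, axis: str, fixed: Mapping | None):
    df = _filter(result.table, fixed)
    if df.empty:
        raise ParameterError(f"no rows match filter {dict(fixed or {})!r}")
    if df[axis].duplicated().any():
        raise ParameterError(
            f"filter does not isolate a single {axis} curve; fix the other axes"
        )
    df = df.sort_values(axis)
    best = df["mi_mean"].max()
    winners = df.loc[df["mi_mean"] == best, axis]
    if len(winners) > 1:
        logger.warning(
            "MI tie along %s between %s; reporting the smallest", axis, list(winners)
        )
    return winners.iloc[0]


def argmax_threshold(result: SweepResult, fixed: Mapping | None = None) -> int:
    """The firing threshold with maximal mean corrected MI (ties -> smaller)."""
    return int(_argmax_along(result, "theta", fixed))


def argmax_connectivity(result: SweepResult, fixed: Mapping | None = None) -> float:
    """Dual read-out: the connectivity rate maximizing mean corrected MI."""
    return float(_argmax_along(result, "r", fixed))


def mean_over_thresholds(result: SweepResult) -> pd.DataFrame:
    """Unweighted mean of MI over the theta grid, per remaining grid point."""
    df = result.table.copy()
    df["alpha"] = df["alpha"].fillna(np.inf)  # keep no-inhibition rows in groupby
    out = (
        df.groupby(["n_kc", "r", "concentration", "alpha"], as_index=False)["mi_mean"]
        .mean()
    )
    out["alpha"] = out["alpha"].replace(np.inf, np.nan)
    return out


# -- persistence and plotting ------------------------------------------------


def write_results(result: SweepResult, path) -> None:
    """Tidy CSV with provenance (version, seed, full config) in header comments."""
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# flyolf_version: {__version__}\n")
            fh.write(f"# seed: {result.config.seed}\n")
            fh.write(f"# config: {json.dumps(result.config.to_dict())}\n")
            result.table.to_csv(fh, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write sweep results to {path}: {exc}") from exc


def read_results(path) -> SweepResult:
    """Read a CSV written by :func:`write_results` (exact round trip)."""
    config = None
    try:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line.lstrip("# ").partition(":")
                if key.strip() == "config":
                    config = ExperimentConfig.from_dict(json.loads(value))
        table = pd.read_csv(path, comment="#")
    except OSError as exc:
        raise OSError(f"could not read sweep results from {path}: {exc}") from exc
    if config is None:
        raise ParameterError(f"{path} lacks the '# config:' provenance line")
    return SweepResult(table=table, config=config)


def render_heatmap(
    result: SweepResult,
    path,
    *,
    fixed: Mapping | None = None,
    title: str | None = None,
):
    """MI surface over (theta, r): thresholds on the x axis, rates on the y axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = _filter(result.table, fixed)
    if df.empty:
        raise ParameterError(f"no rows match filter {dict(fixed or {})!r}")
    pivot = df.pivot_table(index="r", columns="theta", values="mi_mean")
    fig, ax = plt.subplots(figsize=(6, 4.2))
    mesh = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, shading="nearest")
    fig.colorbar(mesh, ax=ax, label="mutual information (bits)")
    ax.set_xlabel("KC firing threshold $\\Theta$")
    ax.set_ylabel("connectivity rate $r$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
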