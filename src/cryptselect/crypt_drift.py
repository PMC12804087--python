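"""Neutral-drift clonal dynamics of intestinal crypt stem cells.

A labelled clone occupying k of the Ns stem-cell positions in a crypt evolves
by stochastic replacement: at rate lambda a replacement event occurs and the
clone expands (k -> k+1) with probability pr or contracts (k -> k-1) with
probability 1-pr, until it is lost (k=0) or fixes in the crypt (k=Ns).
pr = 0.5 is neutral drift; pr above/below 0.5 models positive/negative bias.

Two implementations of the same birth-death chain are provided: an exact
continuous-time Markov-chain solution (matrix exponential of the generator —
no time-discretization error) and a Gillespie event simulator.  The clone
*survival* curve, P(clone not yet lost at time t), is the neutral null
against which tumour decay in the rescue protocols is measured.

The transition propensity kernel w(k) is configurable: the default
``boundary`` kernel (w(k)=1 for 0<k<Ns) reflects a contiguous clone in a
one-dimensional ring of cells, whose two boundaries make the replacement
propensity size-independent; ``percell`` (w(k)=k) scales rates with clone
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm


class DriftError(ValueError):
    pass


def _default_grid() -> np.ndarray:
    return np.arange(1.0, 30.0 + 1e-9, 0.5)


@dataclass
class DriftParams:
    """Parameters of the crypt drift model.

    ns: stem cells per crypt; lam: replacement rate (events per day);
    pr: probability a replacement expands the labelled clone; tau: start of
    the reported time grid (days).  Defaults are the small-intestinal values
    used throughout: ns=5, lam=0.1/day, pr=0.5, tau=1, grid 1..30 by 0.5.
    """

    ns: int = 5
    lam: float = 0.1
    pr: float = 0.5
    tau: float = 1.0
    times: np.ndarray = field(default_factory=_default_grid)
    kernel: str = "boundary"  # boundary: w(k)=1; percell: w(k)=k

    def __post_init__(self) -> None:
        if int(self.ns) < 2:
            raise DriftError("ns must be an integer >= 2")
        self.ns = int(self.ns)
        if self.lam <= 0:
            raise DriftError("lambda must be positive")
        if not 0 < self.pr < 1:
            raise DriftError("pr must be in (0,1)")
        if self.tau < 0:
            raise DriftError("tau must be >= 0")
        if self.kernel not in ("boundary", "percell"):
            raise DriftError(f"unknown kernel {self.kernel!r}")
        self.times = np.asarray(self.times, dtype=float)

    def w(self, k: int) -> float:
        return float(k) if self.kernel == "percell" else 1.0


@dataclass
class DecayCurve:
    """Survival fraction of clones over time (1 at t=0, non-increasing)."""

    times: np.ndarray
    surviving: np.ndarray
    occupancy: np.ndarray | None = None  # (len(times), ns+1) state probabilities


def generator_matrix(params: DriftParams) -> np.ndarray:
    """Generator of the birth-death chain on clone size 0..Ns.

    States 0 and Ns are absorbing (loss and fixation); for 0 < k < Ns the
    clone expands at rate lam*pr*w(k) and contracts at rate lam*(1-pr)*w(k).
    """
    n = params.ns
    q = np.zeros((n + 1, n + 1))
    for k in range(1, n):
        up = params.lam * params.pr * params.w(k)
        down = params.lam * (1 - params.pr) * params.w(k)
        q[k, k + 1] = up
        q[k, k - 1] = down
        q[k, k] = -(up + down)
    return q


def occupancy_at(params: DriftParams, t: float, k0: int = 1) -> np.ndarray:
    """Exact state distribution at time t for a clone starting at size k0."""
    if t < 0:
        raise DriftError("time must be >= 0")
    p0 = np.zeros(params.ns + 1)
    p0[k0] = 1.0
    return p0 @ expm(generator_matrix(params) * t)


def drift_oracle(params: DriftParams, k0: int = 1) -> DecayCurve:
    """Exact clone-survival curve: surviving(t) = 1 - P(state 0 at t).

    Computed by matrix exponentiation of the (Ns+1)-state generator, so there
    is no time-discretization error.  The curve is normalized to 1 at clone
    induction (t=0); params.times only sets the reported grid.
    """
    occ = np.vstack([occupancy_at(params, t, k0=k0) for t in params.times])
    return DecayCurve(
        times=params.times.copy(), surviving=1.0 - occ[:, 0], occupancy=occ
    )


def neutral_fraction_at(params: DriftParams, day: float, k0: int = 1) -> float:
    """Exact surviving fraction at a requested day (1 at day 0)."""
    if day < 0:
        raise DriftError("day must be >= 0")
    if day == 0:
        return 1.0
    return float(1.0 - occupancy_at(params, day, k0=k0)[0])


def fixation_probability(params: DriftParams, k0: int = 1) -> float:
    """Long-time probability the clone fixes (reaches Ns) from size k0.

    For the biased walk with ratio r = (1-pr)/pr this is the classic gambler's
    ruin formula; under neutrality it reduces to k0/Ns.
    """
    n, pr = params.ns, params.pr
    if abs(pr - 0.5) < 1e-12:
        return k0 / n
    r = (1 - pr) / pr
    return (1 - r**k0) / (1 - r**n)


def drift_simulate(
    params: DriftParams, n_clones: int, seed: int, k0: int = 1
) -> tuple[DecayCurve, list[np.ndarray]]:
    """Gillespie simulation of independent clones; empirical survival curve.

    Returns the curve on params.times plus one (event_time, size) trajectory
    array per clone.  Bitwise reproducible for a fixed seed.
    """
    if n_clones < 1:
        raise DriftError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    times = params.times
    alive_at = np.zeros(len(times), dtype=np.int64)
    trajectories: list[np.ndarray] = []
    t_max = float(times[-1])
    for _ in range(n_clones):
        t, k = 0.0, k0
        events = [(0.0, k0)]
        while 0 < k < params.ns:
            rate = params.lam * params.w(k)
            t += rng.exponential(1.0 / rate)
            if t > t_max:
                break
            k += 1 if rng.random() < params.pr else -1
            events.append((t, k))
        traj = np.array(events)
        trajectories.append(traj)
        # clone size at each grid time: last event at or before the time
        idx = np.searchsorted(traj[:, 0], times, side="right") - 1
        alive_at += traj[idx, 1] > 0
    return (
        DecayCurve(times=times.copy(), surviving=alive_at / n_clones),
        trajectories,
    )


def curve_frame(curve: DecayCurve):
    import pandas as pd

    return pd.DataFrame({"time": curve.times, "surviving_fraction": curve.surviving})
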