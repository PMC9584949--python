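"""Non-spatial branching-process form of the single-progenitor model.

One clone starts from a single progenitor. Progenitors divide at rate
``lambda`` with outcomes PP / PD / DD at probabilities
``r(1+delta) / 1-2r / r(1-delta)``; differentiating basal cells leave the
basal layer at rate ``Gamma``. The progenitor count is an autonomous
branching process whose mean grows as ``exp(2 r lambda delta t)``; the
whole model is simulated exactly (Gillespie) and serves both as the
engine of the fate-imbalance estimator and as a brute-force oracle for
the spatial cellular automaton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .params import SPParams

__all__ = [
    "CloneSizePath",
    "gillespie_clone",
    "simulate_clones",
    "mean_surviving_size",
    "growth_slope_analytic",
    "progenitor_count_pmf",
]


@dataclass(frozen=True)
class CloneSizePath:
    """Event-time trajectory of one clone.

    ``times`` holds t=0 and every event time; ``progenitors`` and
    ``differentiating`` hold basal counts immediately after each time.
    """

    times: np.ndarray
    progenitors: np.ndarray
    differentiating: np.ndarray

    def at(self, t: float) -> tuple[int, int]:
        """Basal (progenitor, differentiating) counts at time ``t``."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.progenitors[i]), int(self.differentiating[i])


def gillespie_clone(
    params: SPParams, t_max: float, rng: np.random.Generator
) -> CloneSizePath:
    """Exact stochastic simulation of a single clone from one progenitor.

    Returns the full event path up to ``t_max``. For batches use
    :func:`simulate_clones`, which vectorizes across clones.
    """
    lam, gam = params.division_rate, params.stratification_rate
    p_pp, p_pd, _ = params.outcome_probs()
    t, p, d = 0.0, 1, 0
    times, ps, ds = [0.0], [1], [0]
    while p + d > 0:
        rate = lam * p + gam * d
        t += rng.exponential(1.0 / rate)
        if t >= t_max:
            break
        if rng.random() < lam * p / rate:  # division
            u = rng.random()
            if u < p_pp:
                p += 1
            elif u < p_pp + p_pd:
                d += 1
            else:
                p -= 1
                d += 2
        else:  # stratification
            d -= 1
        times.append(t)
        ps.append(p)
        ds.append(d)
    return CloneSizePath(np.asarray(times), np.asarray(ps), np.asarray(ds))


def simulate_clones(
    params: SPParams,
    times: np.ndarray,
    n_clones: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_clones`` independent clones, recording at ``times``.

    Vectorized exact simulation: every iteration advances all clones that
    still have events before the last record time. Returns integer arrays
    ``(progenitors, differentiating)`` of shape ``(n_clones, len(times))``.
    Deterministic for a given seed.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty strictly increasing 1-d array")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lam, gam = params.division_rate, params.stratification_rate
    p_pp, p_pd, _ = params.outcome_probs()
    n_t = len(times)
    t_max = times[-1]

    P = np.ones(n_clones, dtype=np.int64)
    D = np.zeros(n_clones, dtype=np.int64)
    t = np.zeros(n_clones)
    next_rec = np.zeros(n_clones, dtype=np.int64)
    P_rec = np.zeros((n_clones, n_t), dtype=np.int64)
    D_rec = np.zeros((n_clones, n_t), dtype=np.int64)
    if times[0] == 0.0:
        P_rec[:, 0] = 1
        next_rec[:] = 1

    active = np.ones(n_clones, dtype=bool)
    idx_all = np.arange(n_clones)
    while True:
        idx = idx_all[active]
        if idx.size == 0:
            break
        p, d = P[idx], D[idx]
        rate = lam * p + gam * d
        t_new = t[idx] + rng.exponential(1.0, size=idx.size) / rate

        # record the pre-event state at every record time crossed
        while True:
            nr = next_rec[idx]
            m = (nr < n_t) & (t_new > times[np.minimum(nr, n_t - 1)])
            if not m.any():
                break
            rows, cols = idx[m], nr[m]
            P_rec[rows, cols] = P[rows]
            D_rec[rows, cols] = D[rows]
            next_rec[rows] = cols + 1

        done = next_rec[idx] >= n_t
        live = ~done
        idx, p, d, rate = idx[live], p[live], d[live], rate[live]
        t[idx] = t_new[live]
        if idx.size:
            u = rng.random(idx.size)
            div = u * rate < lam * p
            v = rng.random(idx.size)
            pp = div & (v < p_pp)
            pd = div & ~pp & (v < p_pp + p_pd)
            dd = div & ~pp & ~pd
            P[idx[pp]] += 1
            D[idx[pd]] += 1
            P[idx[dd]] -= 1
            D[idx[dd]] += 2
            strat = ~div
            D[idx[strat]] -= 1
            # extinct clones stay (0, 0) at every later record time
            dead = idx[(P[idx] == 0) & (D[idx] == 0)]
            if dead.size:
                next_rec[dead] = n_t
                active[dead] = False
        active &= next_rec < n_t
    return P_rec, D_rec


def mean_surviving_size(
    params: SPParams,
    times: np.ndarray,
    n_clones: int,
    seed: int | np.random.Generator = 0,
    survivors_only: bool = True,
) -> np.ndarray:
    """Mean basal cells per clone at each time.

    "Average clone size" follows lineage-tracing practice: the mean of
    progenitor + differentiating basal counts among clones that still hold
    at least one basal cell ("surviving"); ``survivors_only=False`` averages
    over all induced clones instead. Times with zero survivors yield NaN
    with a warning.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    P, D = simulate_clones(params, np.asarray(times, dtype=float), n_clones, seed)
    size = P + D
    if not survivors_only:
        return size.mean(axis=0)
    alive = size > 0
    n_alive = alive.sum(axis=0)
    if np.any(n_alive == 0):
        warnings.warn("all clones extinct at some record times; mean undefined (NaN)")
    with np.errstate(invalid="ignore"):
        return np.where(n_alive > 0, size.sum(axis=0) / np.maximum(n_alive, 1), np.nan)


def growth_slope_analytic(params: SPParams) -> float:
    """Asymptotic growth rate of ln(mean clone size): ``2 r lambda delta`` /week."""
    return params.growth_rate()


def progenitor_count_pmf(
    params: SPParams, t: float, max_count: int = 60
) -> np.ndarray:
    """Exact progenitor-count distribution at time ``t`` by master-equation
    integration on the truncated state space {0, ..., max_count}.

    The progenitor count is autonomous: up-rate ``lambda r (1+delta) p``,
    down-rate ``lambda r (1-delta) p``. Used as an independent oracle for
    the Gillespie samplers; the truncation must dominate the mass at ``t``.
    """
    lam, r, d = params.division_rate, params.r, params.delta
    n = max_count + 1
    Q = np.zeros((n, n))
    p = np.arange(n, dtype=float)
    up = lam * r * (1 + d) * p
    down = lam * r * (1 - d) * p
    Q[np.arange(n - 1), np.arange(1, n)] = up[:-1]
    Q[np.arange(1, n), np.arange(n - 1)] = down[1:]
    np.fill_diagonal(Q, -(up + down))
    Q[-1, -1] = -down[-1]  # absorbing-ish top edge; mass must not reach it
    p0 = np.zeros(n)
    p0[1] = 1.0
    return p0 @ expm(Q * t)
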