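"""Spatial single-progenitor model on a hexagonal lattice.

Basal cells live on a periodic hexagonal lattice (default 100 x 100 =
10,000 sites, about 1% of the basal area of an adult mouse oesophagus).
A site holds 0, 1 or 2 cells; pairs arise transiently when a progenitor
divides and both daughters occupy the mother's site. Pairs resolve by
migration into an adjacent empty site when one exists, or by instant
extrusion of a differentiating resident when there is no space; two
progenitors with no space wait, division-blocked, until a neighbouring
site frees up. Mutant progenitors carry a fate imbalance ``delta`` that
is suppressed (multiplied by ``crowding_multiplier``, default 0) while
any of their six neighbouring sites is doubly occupied — the local
crowding feedback that lets mutant clones expand in uncrowded tissue and
stall as the epithelium fills with cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import _ca_kernel
from ._ca_kernel import hex_neighbours, run_ca
from .params import SimConfig, SPParams

__all__ = [
    "LatticeState",
    "Trajectory",
    "draw_division_outcome",
    "effective_imbalance",
    "resolve_double_occupancy",
    "initialize_lattice",
    "simulate",
]

Outcome = Literal["PP", "PD", "DD"]


def draw_division_outcome(
    params: SPParams, effective_delta: float, rng: np.random.Generator
) -> Outcome:
    """Sample a division outcome: PP with probability ``r(1+delta_eff)``,
    DD with ``r(1-delta_eff)``, PD with ``1-2r``."""
    p_pp, p_pd, _ = params.outcome_probs(effective_delta)
    if p_pp > 1.0:
        raise ValueError("r(1+delta) exceeds 1: invalid probability mass")
    u = rng.random()
    if u < p_pp:
        return "PP"
    if u < p_pp + p_pd:
        return "PD"
    return "DD"


def effective_imbalance(
    delta: float, n_double_neighbours: int, crowding_multiplier: float
) -> float:
    """Crowding-modified fate imbalance.

    The bias is untouched with no doubly occupied neighbour and multiplied
    by ``crowding_multiplier`` (default 0: full suppression) as soon as at
    least one of the six neighbouring sites holds a cell pair.
    """
    if not 0 <= n_double_neighbours <= 6:
        raise ValueError("n_double_neighbours must be in 0..6")
    if n_double_neighbours == 0:
        return delta
    return delta * crowding_multiplier


class LatticeState:
    """Mutable lattice state: occupancy, cell type, genotype and clone label.

    Cell type codes: -1 empty slot, 0 progenitor, 1 differentiating.
    Genotype codes: 0 wild type, 1 mutant. Clone label -1 = unlabelled.
    """

    def __init__(self, width: int, height: int):
        self.width = width
        self.height = height
        n = width * height
        self.occ = np.zeros(n, dtype=np.int8)
        self.ctype = np.full((n, 2), -1, dtype=np.int8)
        self.geno = np.zeros((n, 2), dtype=np.int8)
        self.clone = np.full((n, 2), -1, dtype=np.int32)
        self.nbrs = hex_neighbours(width, height)
        self.current_time = 0.0

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def occupancy(self, site: int) -> int:
        return int(self.occ[site])

    def place(self, site: int, ctype: int, geno: int = 0, clone: int = -1) -> None:
        if self.occ[site] >= 2:
            raise ValueError(f"site {site} already holds two cells")
        slot = 0 if self.ctype[site, 0] < 0 else 1
        self.ctype[site, slot] = ctype
        self.geno[site, slot] = geno
        self.clone[site, slot] = clone
        self.occ[site] += 1

    def remove(self, site: int, slot: int) -> None:
        if self.ctype[site, slot] < 0:
            raise ValueError("slot is empty")
        if slot == 0:
            self.ctype[site, 0] = self.ctype[site, 1]
            self.geno[site, 0] = self.geno[site, 1]
            self.clone[site, 0] = self.clone[site, 1]
        self.ctype[site, 1] = -1
        self.occ[site] -= 1

    def total_cells(self) -> int:
        return int((self.ctype >= 0).sum())


def resolve_double_occupancy(
    lattice: LatticeState, site: int, rng: np.random.Generator
) -> LatticeState:
    """Resolve a doubly occupied site in place.

    Migration into a uniformly chosen empty neighbour (mover chosen
    uniformly) when space exists; otherwise instant extrusion of a
    differentiating resident (uniform among them, recorded as stratified);
    otherwise — two progenitors with no space — the pair waits.
    """
    if lattice.occ[site] != 2:
        raise ValueError(f"site {site} has occupancy {lattice.occ[site]}, not 2")
    empties = [nb for nb in lattice.nbrs[site] if lattice.occ[nb] == 0]
    if empties:
        target = empties[rng.integers(len(empties))]
        mover = int(rng.integers(2))
        ct = int(lattice.ctype[site, mover])
        g = int(lattice.geno[site, mover])
        cl = int(lattice.clone[site, mover])
        lattice.remove(site, mover)
        lattice.place(int(target), ct, g, cl)
        return lattice
    diff_slots = [k for k in range(2) if lattice.ctype[site, k] == 1]
    if diff_slots:
        out = diff_slots[rng.integers(len(diff_slots))]
        lattice.remove(site, int(out))
    return lattice


def initialize_lattice(
    config: SimConfig, wt: SPParams, rng: np.random.Generator
) -> LatticeState:
    """Fully occupied lattice at the neutral steady state.

    In homeostasis differentiating-cell outflow Gamma*D balances the
    division inflow lambda*P, so D/P = lambda/Gamma and the progenitor
    fraction is Gamma/(lambda+Gamma). A fraction ``induction_fraction`` of
    basal cells is labelled mutant, one clone id per induced cell.
    """
    lat = LatticeState(config.lattice_width, config.lattice_height)
    n = lat.n_sites
    p_prog = wt.stratification_rate / (wt.division_rate + wt.stratification_rate)
    is_prog = rng.random(n) < p_prog
    induced = rng.random(n) < config.induction_fraction
    lat.occ[:] = 1
    lat.ctype[:, 0] = np.where(is_prog, 0, 1)
    lat.geno[:, 0] = induced.astype(np.int8)
    clone_ids = np.full(n, -1, dtype=np.int32)
    clone_ids[induced] = np.arange(int(induced.sum()), dtype=np.int32)
    lat.clone[:, 0] = clone_ids
    return lat


@dataclass(frozen=True)
class Trajectory:
    """Observables of one simulation at each record time."""

    times: np.ndarray
    clones: list  # one DataFrame(clone_id, n_progenitor, n_differentiating, genotype) per time
    labelled_fraction: np.ndarray
    n_surviving: np.ndarray
    total_basal: np.ndarray
    n_doubles: np.ndarray
    n_extruded: np.ndarray
    n_stratified: np.ndarray
    config: SimConfig
    wt: SPParams
    mut: SPParams

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-clone table: (time, clone_id, n_progenitor,
        n_differentiating, genotype)."""
        parts = []
        for t, df in zip(self.times, self.clones):
            d = df.copy()
            d.insert(0, "time", t)
            parts.append(d)
        if not parts:
            return pd.DataFrame(
                columns=["time", "clone_id", "n_progenitor", "n_differentiating", "genotype"]
            )
        return pd.concat(parts, ignore_index=True)


def simulate(config: SimConfig, wt: SPParams, mut: SPParams) -> Trajectory:
    """Run the cellular automaton and record clone-level observables.

    The same (config, wt, mut) triple — in particular ``config.seed`` —
    always yields an identical trajectory.
    """
    rng = np.random.default_rng(config.seed)
    lat = initialize_lattice(config, wt, rng)
    rec = np.asarray(config.record_times, dtype=np.float64)
    out = run_ca(
        config.lattice_width,
        config.lattice_height,
        float(config.duration),
        rec,
        int(config.seed) % (2**31 - 1),
        lat.occ, lat.ctype, lat.geno, lat.clone, lat.nbrs,
        wt.division_rate, wt.stratification_rate, wt.r, wt.delta,
        mut.division_rate, mut.stratification_rate, mut.r, mut.delta,
        float(config.crowding_multiplier),
    )
    ctype_s, geno_s, clone_s, doubles, extruded, stratified = out

    clones = []
    labelled_frac = np.zeros(len(rec))
    n_surv = np.zeros(len(rec), dtype=np.int64)
    total_basal = np.zeros(len(rec), dtype=np.int64)
    for i in range(len(rec)):
        ct = ctype_s[i].ravel()
        cl = clone_s[i].ravel()
        g = geno_s[i].ravel()
        present = ct >= 0
        total = int(present.sum())
        labelled = present & (cl >= 0)
        ids = cl[labelled]
        if ids.size:
            n_ids = int(ids.max()) + 1
            n_p = np.bincount(ids[ct[labelled] == 0], minlength=n_ids)
            n_d = np.bincount(ids[ct[labelled] == 1], minlength=n_ids)
            geno_of = np.zeros(n_ids, dtype=np.int8)
            geno_of[ids] = g[labelled]
            alive = (n_p + n_d) > 0
            df = pd.DataFrame(
                {
                    "clone_id": np.nonzero(alive)[0],
                    "n_progenitor": n_p[alive],
                    "n_differentiating": n_d[alive],
                    "genotype": np.where(geno_of[alive] == 1, "mutant", "wildtype"),
                }
            )
        else:
            df = pd.DataFrame(
                columns=["clone_id", "n_progenitor", "n_differentiating", "genotype"]
            )
        clones.append(df)
        labelled_frac[i] = labelled.sum() / total if total else 0.0
        n_surv[i] = len(df)
        total_basal[i] = total

    return Trajectory(
        times=rec,
        clones=clones,
        labelled_fraction=labelled_frac,
        n_surviving=n_surv,
        total_basal=total_basal,
        n_doubles=doubles,
        n_extruded=extruded,
        n_stratified=stratified,
        config=config,
        wt=wt,
        mut=mut,
    )
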