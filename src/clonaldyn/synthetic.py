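"""Seeded generators for synthetic inputs with the statistical structure
the estimators assume.

Two fixtures are produced: (i) a contiguous grid of 2 mm^2 biopsies
carrying planted clones, where a clone covering a fraction ``a`` of a
sample's area appears at VAF ``a/2`` (diploid heterozygous) before
binomial read-sampling noise at the configured depth (default 600x,
typical of deep targeted sequencing of normal epithelium); and (ii)
matched sample/control binned read counts with negative-binomial noise,
GC-correlated waves, and planted subclonal gains/losses that scale the
expected sample counts by ``1 +/- f/2``.

Every generator is a pure function of (spec, seed); truth tables carry
everything needed to score the downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .branching import mean_surviving_size
from .clone_genomics import MUTATION_COLUMNS, BiopsySample, GenePanel
from .cna import BaitInterval, make_bins
from .params import SimConfig, SPParams
from .progenitor_ca import Trajectory, simulate

__all__ = [
    "PlantedClone",
    "GridFixtureSpec",
    "PlantedCNA",
    "GenomeFixtureSpec",
    "gen_biopsy_grid",
    "burden_grid_spec",
    "gen_cna_readset",
    "gen_tracing_dataset",
    "DEFAULT_CHROM_SIZES",
]

#: Scaled-down mouse-like chromosome set used by default fixtures.
DEFAULT_CHROM_SIZES: Mapping[str, int] = {
    "1": 150_000_000,
    "2": 120_000_000,
    "3": 90_000_000,
    "X": 60_000_000,
}


@dataclass(frozen=True)
class PlantedClone:
    """A clone planted on the biopsy grid.

    ``coverage`` maps (grid_row, grid_col) to the fraction of that
    sample's area the clone occupies; per-sample VAF before noise is half
    that fraction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "missense"
    coverage: Mapping[tuple, float] = field(default_factory=dict)

    def __post_init__(self):
        for (r, c), frac in self.coverage.items():
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"coverage fraction must be in (0, 1], got {frac}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GridFixtureSpec:
    n_rows: int
    n_cols: int
    clones: tuple = ()
    area: float = 2.0
    depth: int | None = 600  # None = noise-free VAFs
    seed: int = 0

    def __post_init__(self):
        for cl in self.clones:
            for (r, c) in cl.coverage:
                if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                    raise ValueError(
                        f"clone {cl.key} placed outside the grid at ({r}, {c})"
                    )


def gen_biopsy_grid(spec: GridFixtureSpec) -> tuple[list[BiopsySample], pd.DataFrame]:
    """Emit the biopsy grid and a truth table.

    Truth columns: chrom, pos, ref, alt, gene, consequence, sample_id,
    grid_row, grid_col, true_vaf, true_area_mm2 (the clone's total planted
    area, repeated on each member row).
    """
    rng = np.random.default_rng(spec.seed)
    per_sample: dict[tuple, list[dict]] = {
        (r, c): [] for r in range(spec.n_rows) for c in range(spec.n_cols)
    }
    truth_rows = []
    for cl in spec.clones:
        total_area = sum(cl.coverage.values()) * spec.area
        for (r, c), frac in sorted(cl.coverage.items()):
            true_vaf = 0.5 * frac
            if spec.depth is None:
                vaf = true_vaf
            else:
                vaf = rng.binomial(spec.depth, true_vaf) / spec.depth
            rec = {
                "chrom": cl.chrom, "pos": cl.pos, "ref": cl.ref, "alt": cl.alt,
                "vaf": vaf, "gene": cl.gene, "consequence": cl.consequence,
            }
            per_sample[(r, c)].append(rec)
            truth_rows.append(
                {
                    "chrom": cl.chrom, "pos": cl.pos, "ref": cl.ref, "alt": cl.alt,
                    "gene": cl.gene, "consequence": cl.consequence,
                    "sample_id": f"S{r}_{c}", "grid_row": r, "grid_col": c,
                    "true_vaf": true_vaf, "true_area_mm2": total_area,
                }
            )
    samples = []
    for (r, c), recs in sorted(per_sample.items()):
        df = pd.DataFrame(recs, columns=MUTATION_COLUMNS)
        samples.append(
            BiopsySample(f"S{r}_{c}", r, c, area=spec.area, mutations=df)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence", "sample_id",
                 "grid_row", "grid_col", "true_vaf", "true_area_mm2"],
    )
    return samples, truth


def burden_grid_spec(
    n_rows: int,
    n_cols: int,
    burden_per_mb: float,
    footprint: int,
    muts_per_sample: int = 4,
    depth: int | None = None,
    seed: int = 0,
) -> tuple[GridFixtureSpec, GenePanel]:
    """Grid spec planting a uniform synonymous burden.

    Each sample receives ``muts_per_sample`` private synonymous mutations
    whose cell fractions sum to ``burden_per_mb * footprint / 1e6``, so
    the burden estimator inverts the construction exactly in noise-free
    mode."""
    target_cells = burden_per_mb * footprint / 1e6
    frac = target_cells / muts_per_sample
    if not 0 < frac <= 1:
        raise ValueError("per-mutation cell fraction outside (0, 1]; adjust inputs")
    clones = []
    pos = 1000
    for r in range(n_rows):
        for c in range(n_cols):
            for k in range(muts_per_sample):
                clones.append(
                    PlantedClone(
                        chrom="17", pos=pos, ref="C", alt="T",
                        gene="PANEL", consequence="synonymous",
                        coverage={(r, c): frac},
                    )
                )
                pos += 10
    spec = GridFixtureSpec(n_rows, n_cols, tuple(clones), depth=depth, seed=seed)
    return spec, GenePanel(genes=("PANEL",), synonymous_footprint=footprint)


@dataclass(frozen=True)
class PlantedCNA:
    chrom: str
    start: int
    end: int
    direction: str  # 'gain' or 'loss'
    cell_fraction: float

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if not 0.0 < self.cell_fraction <= 1.0:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def expected_ratio(self) -> float:
        sign = 1.0 if self.direction == "gain" else -1.0
        return 1.0 + sign * self.cell_fraction / 2.0


@dataclass(frozen=True)
class GenomeFixtureSpec:
    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    events: tuple = ()
    baits: tuple = ()
    bin_width: int = 1_000_000
    # deep targeted panels put a sizeable share of reads off-bait; at
    # thousands-fold on-target depth the off-target genome sits at a few
    # tenths of 1x coverage, ~2000 reads per Mb bin with 150 bp reads
    depth_per_bin: float = 2000.0
    nb_dispersion: float | None = 0.1  # None = noise-free (counts = their means)
    gc_wave_amplitude: float = 0.0  # sample-library GC response (logR units-ish)
    gc_wave_amplitude_control: float = 0.0
    seed: int = 0

    def __post_init__(self):
        spans: dict[str, list] = {}
        for ev in self.events:
            if ev.chrom not in self.chrom_sizes:
                raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
            if ev.end > self.chrom_sizes[ev.chrom]:
                raise ValueError(f"event {ev} extends beyond chromosome end")
            for a, b in spans.get(ev.chrom, []):
                if ev.start < b and a < ev.end:
                    raise ValueError("planted events overlap")
            spans.setdefault(ev.chrom, []).append((ev.start, ev.end))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = (1 + dispersion) * mu (Poisson at 0).

    ``dispersion`` is the extra-Poisson variance fraction: shallow
    sequencing bin counts are close to Poisson with a modest inflation
    from mappability and library effects.
    """
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = mean / dispersion  # var = mu + mu^2/n = mu (1 + dispersion)
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_cna_readset(
    spec: GenomeFixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Matched sample/control bin counts plus the event truth table.

    Control counts are negative binomial around ``depth_per_bin`` scaled
    by each bin's width; sample means are additionally scaled by
    ``1 +/- f/2`` inside planted events. Each library responds to the
    shared GC field with its own amplitude (defaults: sample only), so a
    residual GC wave survives into the sample/control ratio the way
    library-specific GC bias does in real data.
    """
    rng = np.random.default_rng(spec.seed)
    bins = make_bins(dict(spec.chrom_sizes), spec.bin_width)
    mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
    # smooth GC field: two incommensurate waves + a little jitter
    gc = (
        0.45
        + 0.05 * np.sin(2 * np.pi * mids / 37e6)
        + 0.03 * np.sin(2 * np.pi * mids / 11e6 + 1.0)
        + rng.normal(0.0, 0.002, len(bins))
    )
    bins["gc"] = gc
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    base = spec.depth_per_bin * widths / spec.bin_width

    scale = np.ones(len(bins))
    for ev in spec.events:
        hit = (
            (bins["chrom"] == ev.chrom)
            & (bins["start"] < ev.end)
            & (bins["end"] > ev.start)
        ).to_numpy()
        scale[hit] = ev.expected_ratio

    gc_dev = gc - gc.mean()
    mu_control = base * np.exp2(spec.gc_wave_amplitude_control * gc_dev / np.std(gc_dev))
    mu_sample = base * scale * np.exp2(spec.gc_wave_amplitude * gc_dev / np.std(gc_dev))

    control = bins[["chrom", "start", "end"]].copy()
    sample = bins[["chrom", "start", "end"]].copy()
    if spec.nb_dispersion is None:
        control["count"] = mu_control
        sample["count"] = mu_sample
    else:
        control["count"] = _nb_draw(rng, mu_control, spec.nb_dispersion)
        sample["count"] = _nb_draw(rng, mu_sample, spec.nb_dispersion)
    control["gc"] = gc
    sample["gc"] = gc

    truth = pd.DataFrame(
        [
            {
                "chrom": ev.chrom, "start": ev.start, "end": ev.end,
                "direction": ev.direction, "cell_fraction": ev.cell_fraction,
                "expected_logr": float(np.log2(ev.expected_ratio)),
                "length_mb": (ev.end - ev.start) / 1e6,
            }
            for ev in spec.events
        ],
        columns=["chrom", "start", "end", "direction", "cell_fraction",
                 "expected_logr", "length_mb"],
    )
    return sample, control, truth


def random_baits(
    chrom_sizes: Mapping[str, int],
    n_per_chrom: int = 200,
    length: int = 400,
    seed: int = 0,
) -> list[BaitInterval]:
    """Exon-sized capture baits scattered uniformly (for targeted-mode
    fixtures)."""
    rng = np.random.default_rng(seed)
    baits = []
    for chrom, size in chrom_sizes.items():
        starts = np.sort(rng.integers(0, size - length, n_per_chrom))
        for s in starts:
            baits.append(BaitInterval(chrom, int(s), int(s) + length))
    return baits


def gen_tracing_dataset(
    wt: SPParams,
    mut: SPParams,
    config: SimConfig,
    oracle_clones: int = 0,
) -> dict:
    """Small lineage-tracing fixture: one CA trajectory, optionally with
    matching non-spatial oracle means at the same record times."""
    out: dict = {"trajectory": simulate(config, wt, mut)}
    if oracle_clones > 0:
        times = np.asarray(config.record_times, dtype=float)
        pos = times[times > 0]
        out["oracle_times"] = pos
        out["oracle_mean_size"] = mean_surviving_size(
            mut, pos, oracle_clones, seed=config.seed
        )
    return out


def trajectory_fixture(seed: int = 0) -> Trajectory:
    """Canned small neutral trajectory for regression tests."""
    wt = SPParams(r=0.1, division_rate=1.9, stratification_rate=3.5, delta=0.0)
    cfg = SimConfig(
        lattice_width=30, lattice_height=30, induction_fraction=0.05,
        duration=12.0, record_times=(0.0, 3.0, 6.0, 12.0), seed=seed,
    )
    return simulate(cfg, wt, wt)
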