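"""Estimators over gridded-biopsy deep-sequencing mutation tables.

A tissue is cut into a contiguous grid of small (default 2 mm^2) samples
that are deep-sequenced individually. Each somatic mutation is observed
per sample with a variant allele frequency (VAF); under diploid
heterozygosity the fraction of cells carrying the mutation is about
2 x VAF, so VAF x area and min(2 x VAF, 1) x area bound the clone's
areal extent. Clones larger than one sample appear as the same mutation
key in adjacent samples, so shared mutations are merged across samples
closer than a distance threshold (default 3 mm: shared-mutation counts
plateau beyond that) into single clonal events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationCall",
    "BiopsySample",
    "MergedCloneEvent",
    "GenePanel",
    "MUTATION_COLUMNS",
    "samples_to_frame",
    "shared_mutation_decay",
    "merge_clones",
    "clone_area_bounds",
    "gene_tissue_fraction",
    "mutation_burden",
    "clone_density",
    "rank_tp53_consequence",
    "DOMINANT_NEGATIVE_TP53",
]

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "vaf", "gene", "consequence"]

#: TP53 protein changes with documented dominant-negative activity.
DOMINANT_NEGATIVE_TP53 = frozenset(
    {"p.R175H", "p.Y220C", "p.M237L", "p.R248Q", "p.R248W", "p.R273H", "p.R282W", "p.R249S"}
)

CONSEQUENCES = {"synonymous", "missense", "nonsense", "essential_splice", "indel", "other"}


@dataclass(frozen=True)
class MutationCall:
    """One SNV/indel observed in one biopsy. ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    gene: str = ""
    consequence: str = "other"
    protein_change: str = ""

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class BiopsySample:
    """One gridded biopsy: grid position, area, and its mutation table."""

    sample_id: str
    grid_row: int
    grid_col: int
    area: float = 2.0
    mutations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MUTATION_COLUMNS)
    )

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("sample area must be positive")
        missing = [c for c in MUTATION_COLUMNS if c not in self.mutations.columns]
        if missing:
            raise ValueError(f"mutation table lacks columns: {missing}")

    @classmethod
    def from_calls(cls, sample_id, grid_row, grid_col, calls: Iterable[MutationCall],
                   area: float = 2.0) -> "BiopsySample":
        rows = [
            {
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "vaf": c.vaf, "gene": c.gene, "consequence": c.consequence,
            }
            for c in calls
        ]
        df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
        return cls(sample_id, grid_row, grid_col, area, df)


@dataclass(frozen=True)
class MergedCloneEvent:
    """A mutation merged across contiguous samples into one clonal event."""

    key: tuple  # (chrom, pos, ref, alt)
    sample_ids: tuple
    aggregated_vaf: float
    area_lower: float  # sum of vaf_i * area_i over member samples, mm^2
    area_upper: float  # sum of min(2 vaf_i, 1) * area_i, mm^2
    gene: str = ""
    consequence: str = "other"


@dataclass(frozen=True)
class GenePanel:
    """Targeted bait set: gene symbols plus the synonymous footprint
    (bases within the bait set at which a synonymous call is possible)."""

    genes: tuple
    synonymous_footprint: int

    def __post_init__(self):
        if self.synonymous_footprint <= 0:
            raise ValueError("synonymous_footprint must be positive")


# --------------------------------------------------------------------------
# helpers

def samples_to_frame(samples: Sequence[BiopsySample]) -> pd.DataFrame:
    parts = []
    for s in samples:
        if not len(s.mutations):
            continue
        df = s.mutations.copy()
        df.insert(0, "sample_id", s.sample_id)
        df.insert(1, "grid_row", s.grid_row)
        df.insert(2, "grid_col", s.grid_col)
        df.insert(3, "area", s.area)
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=["sample_id", "grid_row", "grid_col", "area", *MUTATION_COLUMNS])
    return pd.concat(parts, ignore_index=True)


def _grid_distance(s1: BiopsySample, s2: BiopsySample, step_mm: float = 2.0) -> float:
    """Centre-to-centre Euclidean distance; grid step defaults to 2 mm."""
    return step_mm * float(
        np.hypot(s1.grid_row - s2.grid_row, s1.grid_col - s2.grid_col)
    )


def _check_no_duplicates(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["sample_id", "chrom", "pos", "ref", "alt"])
    if dup.any():
        bad = df.loc[dup, ["sample_id", "chrom", "pos", "ref", "alt"]].iloc[0]
        raise ValueError(f"duplicate (sample, mutation) row: {tuple(bad)}")


# --------------------------------------------------------------------------
# operations

def shared_mutation_decay(
    samples: Sequence[BiopsySample], step_mm: float = 2.0
) -> pd.DataFrame:
    """Mean number of shared mutation keys between sample pairs, by distance.

    This is the diagnostic used to choose the merge threshold: adjacent
    samples share clones that straddle their boundary, so shared counts
    decay with distance and plateau at the background level.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    keys = [
        set(map(tuple, s.mutations[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
        for s in samples
    ]
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            d = _grid_distance(samples[i], samples[j], step_mm)
            rows.append((round(d, 6), len(keys[i] & keys[j])))
    df = pd.DataFrame(rows, columns=["distance_mm", "shared"])
    out = (
        df.groupby("distance_mm")["shared"]
        .agg(mean_shared="mean", n_pairs="size")
        .reset_index()
        .sort_values("distance_mm", ignore_index=True)
    )
    return out


def merge_clones(
    samples: Sequence[BiopsySample], threshold: float = 3.0, step_mm: float = 2.0
) -> list[MergedCloneEvent]:
    """Merge each mutation across samples closer than ``threshold`` mm.

    For one mutation key, samples carrying it form a graph with edges
    between samples at centre distance strictly below the threshold (with
    the default 2 mm grid step, edge neighbours at 2 mm and diagonal
    neighbours at 2.83 mm both merge); every connected component becomes
    one :class:`MergedCloneEvent` whose VAF is the area-weighted mean over
    its member samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = samples_to_frame(samples)
    _check_no_duplicates(df)
    by_id = {s.sample_id: s for s in samples}
    events: list[MergedCloneEvent] = []
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        members = grp.reset_index(drop=True)
        n = len(members)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                si, sj = by_id[members.sample_id[i]], by_id[members.sample_id[j]]
                if _grid_distance(si, sj, step_mm) < threshold:
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        for comp in comps.values():
            rows = members.iloc[comp]
            areas = rows["area"].to_numpy(dtype=float)
            vafs = rows["vaf"].to_numpy(dtype=float)
            events.append(
                MergedCloneEvent(
                    key=tuple(key),
                    sample_ids=tuple(sorted(rows["sample_id"])),
                    aggregated_vaf=float((vafs * areas).sum() / areas.sum()),
                    area_lower=float((vafs * areas).sum()),
                    area_upper=float((np.minimum(2 * vafs, 1.0) * areas).sum()),
                    gene=str(rows["gene"].iloc[0]),
                    consequence=str(rows["consequence"].iloc[0]),
                )
            )
    return events


def clone_area_bounds(vaf: float, area: float) -> tuple[float, float]:
    """Clone-area bounds from one sample: (VAF x area, min(2 VAF, 1) x area).

    The factor-of-two range absorbs copy-number uncertainty at the locus.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if area <= 0:
        raise ValueError("area must be positive")
    return vaf * area, min(2.0 * vaf, 1.0) * area


def gene_tissue_fraction(
    samples: Sequence[BiopsySample], gene: str
) -> tuple[float, float]:
    """Fraction of the tissue covered by clones mutant in ``gene``.

    Per biopsy, the VAFs (lower) or 2 x VAFs (upper) of non-synonymous
    mutations in the gene are summed and capped at 1.0; the tissue
    fraction is the mean over all biopsies, zero biopsies included.
    Returns ``(lower, upper)``.
    """
    if not samples:
        raise ValueError("need at least one sample")
    lowers, uppers = [], []
    seen = False
    for s in samples:
        m = s.mutations
        sel = m[(m["gene"] == gene) & (m["consequence"] != "synonymous")]
        if len(sel):
            seen = True
        v = sel["vaf"].to_numpy(dtype=float)
        lowers.append(min(v.sum(), 1.0))
        uppers.append(min((2 * v).sum(), 1.0))
    if not seen:
        warnings.warn(f"no non-synonymous mutations in gene {gene!r}; fraction is 0")
    return float(np.mean(lowers)), float(np.mean(uppers))


def mutation_burden(
    samples: Sequence[BiopsySample], panel: GenePanel, double_vaf: bool = True
) -> pd.DataFrame:
    """Synonymous mutation burden per megabase, per sample.

    burden/Mb = sum over synonymous SNVs of min(2 VAF, 1) divided by the
    panel's synonymous footprint, times 1e6. The 2 x VAF factor converts
    allele to cell fraction under the autosomal heterozygous diploid
    assumption; ``double_vaf=False`` gives the VAF-only lower bound.
    Indels never enter the burden (synonymous SNVs only). The returned
    frame carries the tissue mean in ``.attrs['tissue_mean']``.
    """
    rows = []
    any_syn = False
    for s in samples:
        syn = s.mutations[s.mutations["consequence"] == "synonymous"]
        v = syn["vaf"].to_numpy(dtype=float)
        cell_frac = np.minimum(2 * v, 1.0) if double_vaf else v
        rows.append(
            {
                "sample_id": s.sample_id,
                "n_synonymous": len(syn),
                "burden_per_mb": cell_frac.sum() / panel.synonymous_footprint * 1e6,
            }
        )
        any_syn = any_syn or len(syn) > 0
    if not any_syn:
        warnings.warn("no synonymous mutations in any sample; burden is 0")
    df = pd.DataFrame(rows, columns=["sample_id", "n_synonymous", "burden_per_mb"])
    df.attrs["tissue_mean"] = float(df["burden_per_mb"].mean()) if len(df) else 0.0
    return df


def clone_density(n_events: int, total_area: float) -> float:
    """Clonal events per mm^2 of epithelium (e.g. 26 events over 80 mm^2
    of tissue give 0.33 /mm^2 when rounded to two decimals)."""
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    return n_events / total_area


def rank_tp53_consequence(variants) -> str:
    """Most severe TP53 consequence class for one sample.

    Severity order: ``dominant_negative`` (protein change on the
    literature list), then ``nonsense``, ``missense``, ``other``; an empty
    input gives ``none``. Accepts MutationCall objects or a DataFrame with
    ``consequence`` and optional ``protein_change`` columns.
    """
    if isinstance(variants, pd.DataFrame):
        records = variants.to_dict("records")
    else:
        records = [
            {"consequence": v.consequence, "protein_change": getattr(v, "protein_change", "")}
            for v in variants
        ]
    if not records:
        return "none"
    classes = set()
    for rec in records:
        if str(rec.get("protein_change", "")) in DOMINANT_NEGATIVE_TP53:
            classes.add("dominant_negative")
        cons = str(rec.get("consequence", "other"))
        if cons in ("nonsense", "missense"):
            classes.add(cons)
        else:
            classes.add("other")
    for cls in ("dominant_negative", "nonsense", "missense", "other"):
        if cls in classes:
            return cls
    return "none"
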