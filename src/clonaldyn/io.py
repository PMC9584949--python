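"""File formats and run manifests.

Conventions: genomic intervals (BED, bins, segments) are 0-based
half-open; per-base mutation positions are 1-based (VCF style). All
tables are plain TSV with a header, written with a deterministic column
order so that read(write(x)) round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .clone_genomics import MUTATION_COLUMNS, BiopsySample, GenePanel, MergedCloneEvent
from .cna import BaitInterval
from .progenitor_ca import Trajectory

__all__ = [
    "read_bed",
    "read_chrom_sizes",
    "read_mutation_table",
    "read_gene_panel",
    "read_bins",
    "write_events",
    "read_events",
    "write_seg",
    "read_seg",
    "write_trajectory",
    "RunManifest",
]

MUTATION_TABLE_COLUMNS = [
    "sample_id", "grid_row", "grid_col", "chrom", "pos", "ref", "alt",
    "vaf", "gene", "consequence",
]

EVENT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "n_samples",
    "sample_ids", "aggregated_vaf", "area_lower", "area_upper",
]

SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_bins", "mean_logr", "call",
    "cell_fraction", "length_mb", "retained", "filter_reason",
]


class ParseError(ValueError):
    pass


def read_bed(path) -> list[BaitInterval]:
    """Read a 3+ column BED file into sorted, validated intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.append(BaitInterval(chrom, start, end))
    return sorted(out, key=lambda b: (b.chrom, b.start, b.end))


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            chrom = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length") from exc
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive length")
            if chrom in sizes:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = length
    return sizes


def read_mutation_table(path) -> list[BiopsySample]:
    """Read the long-format mutation TSV into per-sample objects.

    Required columns: sample_id, grid_row, grid_col, chrom, pos, ref,
    alt, vaf, gene, consequence; an optional ``area`` column defaults to
    2 mm^2.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MUTATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    bad = df[(df["vaf"] < 0) | (df["vaf"] > 1)]
    if len(bad):
        raise ParseError(f"{path}: vaf outside [0, 1] in {len(bad)} rows")
    if df.duplicated(subset=["sample_id", "chrom", "pos", "ref", "alt"]).any():
        raise ParseError(f"{path}: duplicate (sample, mutation) rows")
    if "area" not in df.columns:
        df["area"] = 2.0
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        samples.append(
            BiopsySample(
                sample_id=str(sid),
                grid_row=int(grp["grid_row"].iloc[0]),
                grid_col=int(grp["grid_col"].iloc[0]),
                area=float(grp["area"].iloc[0]),
                mutations=grp[MUTATION_COLUMNS].reset_index(drop=True),
            )
        )
    return samples


def write_mutation_table(samples: list[BiopsySample], path) -> None:
    from .clone_genomics import samples_to_frame

    df = samples_to_frame(samples)
    df = df[["sample_id", "grid_row", "grid_col", *MUTATION_COLUMNS, "area"]]
    df.to_csv(path, sep="\t", index=False)


def read_gene_panel(path) -> GenePanel:
    """Panel TSV: lines of ``gene<TAB>.`` plus one ``#footprint=<bp>``
    header line (or a two-column ``footprint`` row)."""
    genes = []
    footprint = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#footprint="):
                footprint = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if fields[0] == "footprint":
                footprint = int(fields[1])
                continue
            genes.append(fields[0])
    if footprint is None:
        raise ParseError(f"{path}: no synonymous footprint declared")
    return GenePanel(genes=tuple(genes), synonymous_footprint=footprint)


def read_bins(path) -> pd.DataFrame:
    """Bin-count TSV: chrom, start, end, count and optionally gc/masked."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end", "count"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_events(events: list[MergedCloneEvent], path) -> None:
    rows = [
        {
            "chrom": e.key[0], "pos": e.key[1], "ref": e.key[2], "alt": e.key[3],
            "gene": e.gene, "consequence": e.consequence,
            "n_samples": len(e.sample_ids), "sample_ids": ";".join(e.sample_ids),
            "aggregated_vaf": e.aggregated_vaf,
            "area_lower": e.area_lower, "area_upper": e.area_upper,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[MergedCloneEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for rec in df.to_dict("records"):
        out.append(
            MergedCloneEvent(
                key=(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"]),
                sample_ids=tuple(str(rec["sample_ids"]).split(";")),
                aggregated_vaf=float(rec["aggregated_vaf"]),
                area_lower=float(rec["area_lower"]),
                area_upper=float(rec["area_upper"]),
                gene="" if pd.isna(rec["gene"]) else str(rec["gene"]),
                consequence=str(rec["consequence"]),
            )
        )
    return out


def write_seg(calls: pd.DataFrame, path, sample: str = "sample") -> None:
    """SEG-style TSV of copy-number calls, retained and filtered alike."""
    df = calls.copy()
    if "sample" not in df.columns:
        df.insert(0, "sample", sample)
    df = df[SEG_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["filter_reason"] = df["filter_reason"].fillna("")
    return df


def write_trajectory(traj: Trajectory, path) -> None:
    """Tidy per-clone TSV: time, clone_id, n_progenitor,
    n_differentiating, genotype."""
    traj.to_frame().to_csv(path, sep="\t", index=False)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    subcommand: str
    parameters: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    code_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, subcommand: str, parameters: dict, seed=None, input_paths=()) -> "RunManifest":
        from . import __version__

        inputs = {}
        for p in input_paths:
            p = Path(p)
            if p.exists():
                inputs[str(p)] = _hash_file(p)
        return cls(
            subcommand=subcommand,
            parameters={k: v for k, v in parameters.items() if not k.startswith("_")},
            seed=seed,
            inputs=inputs,
            code_version=f"clonaldyn {__version__} (python {platform.python_version()})",
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
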