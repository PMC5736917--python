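"""Readers and writers for the pipeline's table formats.

TSV is the canonical dialect (header required, "NA" = missing). Internal
coordinates are 1-based closed; BED export converts to 0-based half-open and
the reader inverts it losslessly. FASTA is read via Biopython.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .events import RecombEvent, events_from_frame, events_to_frame
from .genome import GenomeLayout
from .genotypes import SPORE_COLUMNS, TetradGenotypes

PROBE_REQUIRED = ["probe_id", "chrom", "start", "end", "context"]
GENOTYPE_REQUIRED = ["marker_id", "chrom", "pos"]


@dataclass
class RunConfig:
    """Serializable run parameters shared by the CLI subcommands."""

    seed: int = 0
    quantile: float = 0.10
    replicates_required: int | None = None
    complex_merge_bp: float = 7500.0
    bir_min_bp: float = 5000.0
    window_bp: float = 5000.0
    step_bp: float = 1000.0
    n_sims: int = 1000
    telomere_margin_bp: float = 50_000.0
    centromere_margin_bp: float = 25_000.0

    def __post_init__(self):
        if not (0.0 < self.quantile < 0.5):
            raise ValueError("quantile must be in (0, 0.5)")
        for name in ("complex_merge_bp", "bir_min_bp", "window_bp", "step_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in PROBE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} lacks required columns: {missing}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].head().tolist()
        raise ValueError(f"duplicate probe ids in {path}: {dups}")
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unsortable coordinates in {path}: {exc}") from None
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_probe_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotype_table(path) -> list[TetradGenotypes]:
    df = pd.read_csv(path, sep="\t", na_values=[], keep_default_na=False, dtype=str)
    spore_cols = [c for c in df.columns if c.startswith("spore")]
    if sorted(spore_cols) != list(SPORE_COLUMNS):
        raise ValueError(
            f"genotype table {path} must have exactly four spore columns "
            f"{list(SPORE_COLUMNS)}; found {spore_cols}"
        )
    missing = [c for c in GENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table {path} lacks required columns: {missing}")
    df["pos"] = df["pos"].astype(int)
    if "tetrad" not in df.columns:
        df["tetrad"] = "tetrad1"
    out = []
    for tid, grp in df.groupby("tetrad", sort=False):
        if grp["marker_id"].duplicated().any():
            raise ValueError(f"duplicate markers in tetrad {tid} of {path}")
        out.append(TetradGenotypes.from_frame(grp, str(tid)))
    return out


def write_genotype_table(tetrads, path) -> None:
    pd.concat([t.to_frame() for t in tetrads], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def write_events_table(events: list[RecombEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_events_table(path) -> list[RecombEvent]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return events_from_frame(df)


def write_spots_bed(spots: pd.DataFrame, path) -> None:
    """Spots as BED: 0-based half-open, name=category:temperature,
    score = mean activity x 1000 (clipped to 0..1000)."""
    with open(path, "w") as fh:
        for _, r in spots.iterrows():
            name = f"{r['category']}:{r['temperature'] if r['temperature'] else '.'}"
            score = (
                int(np.clip(round(r["mean_activity"] * 1000), 0, 1000))
                if np.isfinite(r["mean_activity"])
                else 0
            )
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{name}\t{score}\n")


def read_spots_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s0, e0, name, score = line.rstrip("\n").split("\t")[:5]
            cat, _, temp = name.partition(":")
            rows.append(
                (
                    cat,
                    None if temp in (".", "") else temp,
                    chrom,
                    int(s0) + 1,
                    int(e0),
                    int(score) / 1000.0,
                )
            )
    return pd.DataFrame(
        rows, columns=["category", "temperature", "chrom", "start", "end", "mean_activity"]
    )


def read_chromosome_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"name", "length"}
    if not need.issubset(df.columns):
        raise ValueError(f"chromosome table {path} needs columns {sorted(need)}")
    if "centromere" not in df.columns:
        df["centromere"] = df["length"] // 2
    return df


def layout_from_tables(chromosomes: pd.DataFrame, markers=None, probes=None) -> GenomeLayout:
    if markers is None:
        markers = pd.DataFrame(columns=["marker_id", "chrom", "pos"])
    if probes is None:
        probes = pd.DataFrame(columns=["probe_id", "chrom", "start", "end", "context"])
    return GenomeLayout(chromosomes=chromosomes, markers=markers, probes=probes)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
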