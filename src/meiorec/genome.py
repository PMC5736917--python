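"""Genome layouts: chromosomes, SNP marker maps, and tiling-array probes.

A :class:`GenomeLayout` is the shared coordinate system for both kinds of
simulated data: four-spore SNP genotype tables (markers) and Spo11 ChIP-chip
probe tables (probes). Coordinates are 1-based and intervals closed, per SGD
convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import yeast_chromosome_table

#: Gene-context classes assigned to probes. Intergenic probes are split by the
#: transcriptional orientation of the flanking genes: divergent promoters
#: (class 1), convergent terminators (class 2), and tandem ("same direction",
#: class 3).
PROBE_CONTEXTS = (
    "intragenic",
    "intergenic_divergent",
    "intergenic_convergent",
    "intergenic_tandem",
)

#: Default intergenic:intragenic probe ratio on the array (about 1:2.7).
DEFAULT_INTERGENIC_TO_INTRAGENIC = 1.0 / 2.7

#: Default divergent:convergent:tandem ratio among intergenic probes (2.4:1:3.4).
DEFAULT_INTERGENIC_CLASS_RATIOS = (2.4, 1.0, 3.4)


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosomes plus ordered marker and probe maps.

    Attributes
    ----------
    chromosomes : DataFrame with columns ``name``, ``length``, ``centromere``.
    markers : DataFrame with columns ``marker_id``, ``chrom``, ``pos``,
        sorted by chromosome (in table order) then position.
    probes : DataFrame with columns ``probe_id``, ``chrom``, ``start``,
        ``end``, ``context``; intervals are non-overlapping per chromosome.
    """

    chromosomes: pd.DataFrame
    markers: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = self.chrom_lengths()
        cen = dict(zip(self.chromosomes["name"], self.chromosomes["centromere"]))
        if (self.chromosomes["length"] <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        for name, c in cen.items():
            if not (1 <= c <= lengths[name]):
                raise ValueError(f"centromere of {name} outside chromosome")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.all(np.diff(pos) > 0)):
                raise ValueError(f"marker positions not sorted/unique on {chrom}")
            if pos.size and (pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker position outside {chrom}")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if np.any(e < s):
                raise ValueError(f"probe end < start on {chrom}")
            if s.size > 1 and np.any(s[1:] <= e[:-1]):
                raise ValueError(f"overlapping probes on {chrom}")
            if s.size and (s[0] < 1 or e[-1] > lengths[chrom]):
                raise ValueError(f"probe interval outside {chrom}")

    # -- convenience accessors -------------------------------------------------
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["name"], self.chromosomes["length"]))

    def centromeres(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["name"], self.chromosomes["centromere"]))

    @property
    def total_length(self) -> int:
        return int(self.chromosomes["length"].sum())

    def marker_positions(self, chrom: str) -> np.ndarray:
        return self.markers.loc[self.markers["chrom"] == chrom, "pos"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_probes(self) -> int:
        return len(self.probes)


def _jittered_grid(
    length: int, spacing: int, jitter: float, rng: np.random.Generator, margin: int = 0
) -> np.ndarray:
    """Regular grid at ``spacing`` with per-point jitter below spacing/2.

    Jitter strictly less than half the spacing keeps positions sorted and
    unique; ``margin`` reserves room at the right edge (for probe length).
    """
    grid = np.arange(spacing, length + 1 - margin, spacing, dtype=np.int64)
    if jitter > 0:
        j = min(int(jitter * spacing), (spacing - 1) // 2 - margin // 2)
        if j > 0:
            grid = grid + rng.integers(-j, j + 1, size=grid.size)
    return np.clip(grid, 1, length - margin)


def make_genome_layout(
    n_chromosomes: int = 16,
    lengths: Sequence[int] | None = None,
    marker_spacing: int = 1000,
    probe_spacing: int = 1000,
    seed: int | None = None,
    *,
    centromeres: Sequence[int] | None = None,
    chrom_names: Sequence[str] | None = None,
    probe_length: int = 60,
    jitter: float = 0.25,
    intergenic_to_intragenic: float = DEFAULT_INTERGENIC_TO_INTRAGENIC,
    intergenic_class_ratios: Sequence[float] = DEFAULT_INTERGENIC_CLASS_RATIOS,
) -> GenomeLayout:
    """Build a genome layout with jittered ~evenly spaced markers and probes.

    Defaults mirror the yeast experimental design: 16 chromosomes (~12 Mb
    total, bundled SGD lengths/centromeres), markers roughly 1 kb apart
    (~13,000 SNPs), 60-base probes roughly 1 kb apart (~15,000
    oligonucleotides), intergenic:intragenic probe ratio 1:2.7 and intergenic
    class ratio 2.4:1:3.4 (divergent:convergent:tandem).

    Parameters
    ----------
    jitter : fraction of the spacing used as the half-width of the uniform
        positional jitter; 0 gives an exact grid.
    """
    if marker_spacing <= 0 or probe_spacing <= 0:
        raise ValueError("marker/probe spacing must be positive")
    if probe_length <= 0 or probe_length >= probe_spacing:
        raise ValueError("probe_length must be in (0, probe_spacing)")
    if intergenic_to_intragenic <= 0:
        raise ValueError("intergenic_to_intragenic must be positive")

    if lengths is None:
        table = yeast_chromosome_table().head(n_chromosomes)
        names = list(table["name"])
        lens = list(table["length"])
        cens = list(table["centromere"])
    else:
        lens = [int(x) for x in lengths]
        if any(x <= 0 for x in lens):
            raise ValueError("chromosome lengths must be positive")
        names = (
            list(chrom_names)
            if chrom_names is not None
            else [f"chr{i + 1}" for i in range(len(lens))]
        )
        cens = (
            [int(x) for x in centromeres]
            if centromeres is not None
            else [x // 2 for x in lens]
        )
    if marker_spacing >= min(lens) or probe_spacing >= min(lens):
        raise ValueError("spacing must be smaller than the shortest chromosome")

    rng = np.random.default_rng(seed)
    marker_rows, probe_rows = [], []
    p_inter = intergenic_to_intragenic / (1.0 + intergenic_to_intragenic)
    w = np.asarray(intergenic_class_ratios, dtype=float)
    if w.size != 3 or np.any(w <= 0):
        raise ValueError("intergenic_class_ratios must be 3 positive weights")
    ctx_probs = np.concatenate([[1.0 - p_inter], p_inter * w / w.sum()])

    for name, length in zip(names, lens):
        mpos = _jittered_grid(length, marker_spacing, jitter, rng)
        for i, p in enumerate(mpos):
            marker_rows.append((f"{name}_m{i + 1}", name, int(p)))
        pstart = _jittered_grid(length, probe_spacing, jitter, rng, margin=probe_length)
        ctx = rng.choice(len(PROBE_CONTEXTS), size=pstart.size, p=ctx_probs)
        for i, (s, c) in enumerate(zip(pstart, ctx)):
            probe_rows.append(
                (f"{name}_p{i + 1}", name, int(s), int(s) + probe_length - 1, PROBE_CONTEXTS[c])
            )

    chromosomes = pd.DataFrame(
        {"name": names, "length": lens, "centromere": cens}
    )
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chrom", "pos"])
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "start", "end", "context"]
    )
    return GenomeLayout(chromosomes=chromosomes, markers=markers, probes=probes)
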