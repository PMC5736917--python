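"""Four-spore tetrad genotypes over a shared SNP marker map.

Parental-origin calls are encoded as int8: 0 = P1 (the W303-1A-like parent),
1 = P2 (the YJM789-like parent), -1 = missing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

P1, P2, MISSING = 0, 1, -1
CALL_LABELS = {P1: "P1", P2: "P2", MISSING: "NA"}
LABEL_CALLS = {v: k for k, v in CALL_LABELS.items()}

SPORE_COLUMNS = ("spore1", "spore2", "spore3", "spore4")


@dataclass
class TetradGenotypes:
    """Parental-origin calls for the four spores of one meiosis.

    ``markers`` is a DataFrame (marker_id, chrom, pos) sorted by chromosome
    then position; ``calls`` is an int8 array of shape (n_markers, 4).
    """

    tetrad_id: str
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), 4):
            raise ValueError(
                f"tetrad {self.tetrad_id}: calls shape {self.calls.shape} does not "
                f"match {len(self.markers)} markers x 4 spores"
            )
        bad = ~np.isin(self.calls, [P1, P2, MISSING])
        if bad.any():
            raise ValueError(f"tetrad {self.tetrad_id}: invalid origin codes present")

    def copy(self) -> "TetradGenotypes":
        return TetradGenotypes(self.tetrad_id, self.markers, self.calls.copy())

    def to_frame(self) -> pd.DataFrame:
        df = self.markers[["marker_id", "chrom", "pos"]].copy()
        df.insert(0, "tetrad", self.tetrad_id)
        for j, col in enumerate(SPORE_COLUMNS):
            df[col] = [CALL_LABELS[int(v)] for v in self.calls[:, j]]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tetrad_id: str) -> "TetradGenotypes":
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        calls = np.empty((len(df), 4), dtype=np.int8)
        for j, col in enumerate(SPORE_COLUMNS):
            try:
                calls[:, j] = [LABEL_CALLS[v] for v in df[col]]
            except KeyError as exc:
                raise ValueError(
                    f"tetrad {tetrad_id}: genotype value {exc} not in {{P1, P2, NA}}"
                ) from None
        return cls(tetrad_id, df[["marker_id", "chrom", "pos"]], calls)
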