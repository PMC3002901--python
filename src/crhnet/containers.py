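"""Core data containers shared across the pipeline.

All tabular data live in pandas objects; spots/genes are rows, arrays/samples
are columns throughout the package.  Dye orientation is encoded as
``"treated_cy3"`` / ``"treated_cy5"`` (which channel carries the treated
sample on that array).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DYE_LEVELS = ("treated_cy3", "treated_cy5")


def _check_arrays_table(arrays: pd.DataFrame) -> None:
    missing = {"time_h", "dye"} - set(arrays.columns)
    if missing:
        raise ValueError(f"array metadata missing column(s): {sorted(missing)}")
    bad = set(arrays["dye"]) - set(DYE_LEVELS)
    if bad:
        raise ValueError(f"unknown dye orientation value(s): {sorted(bad)}")


@dataclass
class TwoColorArraySet:
    """Raw per-spot two-channel intensities with array/pin/dye metadata.

    Attributes
    ----------
    spots : DataFrame indexed by spot id with a ``print_tip`` column (1-based).
    arrays : DataFrame indexed by array id with ``time_h``, ``dye`` and
        (optionally) ``replicate`` columns.
    cy3, cy5 : DataFrames (spots x arrays) of non-negative intensities.
    mask : boolean DataFrame (spots x arrays); True where the spot is present.
    """

    spots: pd.DataFrame
    arrays: pd.DataFrame
    cy3: pd.DataFrame
    cy5: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        _check_arrays_table(self.arrays)
        for mat in (self.cy3, self.cy5, self.mask):
            if mat.shape != (len(self.spots), len(self.arrays)):
                raise ValueError("intensity matrices must be spots x arrays")
        if (self.cy3.to_numpy() < 0).any() or (self.cy5.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    def copy(self) -> "TwoColorArraySet":
        return TwoColorArraySet(
            self.spots.copy(), self.arrays.copy(), self.cy3.copy(),
            self.cy5.copy(), self.mask.copy(),
        )


@dataclass
class MaMatrix:
    """Per-spot M (oriented log2 ratio) and A (mean log2 intensity) values.

    M is oriented treated minus control using each array's dye orientation;
    A = (log2 I_Cy3 + log2 I_Cy5) / 2.  Entries where ``mask`` is False are
    NaN and excluded from all downstream fits.
    """

    m: pd.DataFrame
    a: pd.DataFrame
    mask: pd.DataFrame
    spots: pd.DataFrame
    arrays: pd.DataFrame

    def __post_init__(self):
        _check_arrays_table(self.arrays)
        present = self.mask.to_numpy()
        for mat in (self.m, self.a):
            if not np.all(np.isfinite(mat.to_numpy()[present])):
                raise ValueError("M/A must be finite wherever mask is True")

    def copy(self) -> "MaMatrix":
        return MaMatrix(
            self.m.copy(), self.a.copy(), self.mask.copy(),
            self.spots.copy(), self.arrays.copy(),
        )


@dataclass
class RatioMatrix:
    """Normalized log2-ratio matrix (genes x samples) with sample factors.

    ``samples`` carries the two design factors: ``time_h`` (5 levels in the
    reference design) and ``dye`` (2 levels, 3 replicates per level within
    each time point).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        _check_arrays_table(self.samples)
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata rows must match matrix columns")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("ratio matrix must be complete (no NaN)")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.samples["time_h"].to_numpy()

    @property
    def dye(self) -> np.ndarray:
        return self.samples["dye"].to_numpy()

    def matrix(self) -> np.ndarray:
        """Values as a plain (genes x samples) float array."""
        return self.values.to_numpy(dtype=float)

    def subset(self, genes) -> "RatioMatrix":
        return RatioMatrix(self.values.loc[list(genes)], self.samples)

    def check_balanced(self) -> None:
        """Assert the balanced 5 x (3 + 3) dye-swap design."""
        counts = self.samples.groupby(["time_h", "dye"]).size()
        if counts.nunique() != 1:
            raise ValueError(
                "unbalanced design: unequal replication across time x dye "
                f"cells\n{counts}"
            )
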