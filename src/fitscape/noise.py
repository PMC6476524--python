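"""Replicate-derived frequency-dependent noise model.

Measurement error in genotype frequencies (sampling, PCR, genetic drift)
depends on the frequency itself, so variance is estimated empirically as a
function of frequency from the 2-biological x 2-technical replicate design.
For every replicate pair (i, j) and timepoint, genotypes are sorted by mean
frequency, binned, and the mean squared frequency difference per bin gives an
interpolated curve s2_ij(f).  Drift is shared within a biological replicate,
so within-pair curves (1,2) and (3,4) see only technical noise while
cross-pairs see technical plus biological noise, and the variance of the
4-replicate mean frequency is

    sigma^2(f) = 1/16 * ((s2_13 + s2_14 + s2_23 + s2_24) - (s2_12 + s2_34)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from fitscape.reads import FrequencyTable, REPLICATES, TIMEPOINTS

#: replicate pairs; (1,2) and (3,4) are within-biological-replicate pairs
PAIRS = tuple(combinations(REPLICATES, 2))
WITHIN_PAIRS = ((1, 2), (3, 4))
CROSS_PAIRS = ((1, 3), (1, 4), (2, 3), (2, 4))


@dataclass
class PairwiseCurve:
    """Binned squared-difference curve s2_ij(f) with the f=0 anchor.

    Interpolation is linear between bin centres; beyond the last bin centre
    the curve continues as a constant.
    """

    f_grid: np.ndarray  # includes the 0 anchor as first element
    s2_values: np.ndarray
    single_bin: bool = False

    def __call__(self, f):
        return np.interp(np.asarray(f, float), self.f_grid, self.s2_values)

    @property
    def anchor(self) -> float:
        return float(self.s2_values[0])


def zero_frequency_anchor(n_i: float, n_j: float) -> float:
    """Squared error assigned at frequency 0: 1/2·((0.5/Ni)² + (0.5/Nj)²)."""
    return 0.5 * ((0.5 / n_i) ** 2 + (0.5 / n_j) ** 2)


def pairwise_squared_difference(
    freqs_i: np.ndarray,
    freqs_j: np.ndarray,
    depth_i: float,
    depth_j: float,
    bin_size: int = 5000,
) -> PairwiseCurve:
    """Binned squared-difference curve for one replicate pair.

    Genotypes are sorted by mean frequency and grouped into bins of
    ``bin_size``; a final partial bin is merged into the previous one.  Per
    bin, the mean frequency and mean squared difference are recorded; the
    f=0 anchor uses the total read numbers of the two replicates.
    """
    fi = np.asarray(freqs_i, float)
    fj = np.asarray(freqs_j, float)
    if fi.shape != fj.shape:
        raise ValueError("replicate frequency vectors differ in length")
    mean = 0.5 * (fi + fj)
    sq = (fi - fj) ** 2
    order = np.argsort(mean, kind="stable")
    mean, sq = mean[order], sq[order]
    n = len(mean)

    edges = list(range(0, n, bin_size))
    single_bin = n < 2 * bin_size
    if len(edges) > 1 and n - edges[-1] < bin_size:
        edges.pop()  # merge final partial bin into the previous one
    edges.append(n)

    centers, values = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        centers.append(mean[lo:hi].mean())
        values.append(sq[lo:hi].mean())

    anchor = zero_frequency_anchor(depth_i, depth_j)
    f_grid = np.concatenate([[0.0], centers])
    s2 = np.concatenate([[anchor], values])
    return PairwiseCurve(f_grid=f_grid, s2_values=s2, single_bin=single_bin)


def combine_variance(curves: dict[tuple[int, int], PairwiseCurve], f_grid=None):
    """Variance of the 4-replicate mean frequency from the six pairwise curves.

    Negative combined values (possible by sampling noise) are clamped from
    below at the combination's own f=0 anchor value.
    """
    if f_grid is None:
        f_grid = np.unique(np.concatenate([c.f_grid for c in curves.values()]))
    f_grid = np.asarray(f_grid, float)
    cross = sum(curves[p](f_grid) for p in CROSS_PAIRS)
    within = sum(curves[p](f_grid) for p in WITHIN_PAIRS)
    sigma2 = (cross - within) / 16.0
    floor = (
        sum(curves[p].anchor for p in CROSS_PAIRS)
        - sum(curves[p].anchor for p in WITHIN_PAIRS)
    ) / 16.0
    floor = max(floor, 0.0) or min(
        c.anchor for c in curves.values()
    ) / 16.0  # all-zero anchors would otherwise give a zero floor
    n_clamped = int(np.sum(sigma2 < floor))
    sigma2 = np.maximum(sigma2, floor)
    return f_grid, sigma2, floor, n_clamped


@dataclass
class NoiseModel:
    """Per-timepoint pairwise curves and the combined variance function."""

    curves: dict[int, dict[tuple[int, int], PairwiseCurve]]
    sigma2_grid: dict[int, tuple[np.ndarray, np.ndarray]]
    floors: dict[int, float]
    bin_size: int = 5000
    n_clamped: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_frequency_table(cls, ft: FrequencyTable, bin_size: int = 5000) -> "NoiseModel":
        curves, grids, floors, clamped = {}, {}, {}, {}
        for t in TIMEPOINTS:
            block = ft.rep_freqs.xs(t, axis=1, level="t")
            per_pair = {}
            for i, j in PAIRS:
                per_pair[(i, j)] = pairwise_squared_difference(
                    block[i].to_numpy(),
                    block[j].to_numpy(),
                    ft.depths[(i, t)],
                    ft.depths[(j, t)],
                    bin_size=bin_size,
                )
            curves[t] = per_pair
            f_grid, sigma2, floor, n_cl = combine_variance(per_pair)
            grids[t] = (f_grid, sigma2)
            floors[t] = floor
            clamped[t] = n_cl
        return cls(curves=curves, sigma2_grid=grids, floors=floors,
                   bin_size=bin_size, n_clamped=clamped)

    def variance(self, f, t: int):
        """sigma^2(f) at timepoint ``t`` (linear interpolation, clamped floor)."""
        grid, sigma2 = self.sigma2_grid[t]
        return np.maximum(np.interp(np.asarray(f, float), grid, sigma2), self.floors[t])

    def to_tsv(self, path) -> None:
        frames = []
        for t in TIMEPOINTS:
            grid, sigma2 = self.sigma2_grid[t]
            df = pd.DataFrame({"t": t, "f": grid, "sigma2": sigma2})
            for pair, curve in self.curves[t].items():
                df[f"s2_{pair[0]}{pair[1]}"] = curve(grid)
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)
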