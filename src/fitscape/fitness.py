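"""Fitness estimation from frequency trajectories.

Genotype frequencies follow f_x(t) = f_x(0)·exp[(s_x - s̄_0t)·t], where the
offsets s̄_0t absorb total population growth.  Without loss of generality
s̄_01 = 0 and t1 = 1; the remaining segment-wide nuisance parameters
(s̄_02, k = t2/t1) are fitted once per segment by an exhaustive grid search
over high-frequency genotypes.  Per genotype, (s, f0) minimise the variance-
weighted squared error of the exponential fit over the three time points,
with the variance sigma^2(f) supplied by the replicate noise model.  Dropout
genotypes (present at t0, absent afterwards) get an upper fitness bound
log(1/max_i N_i^t1).  Fitness is finally rescaled so that 95% of nonsense
genotypes map to 0 and the mode of the extant-genotype distribution maps
to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from fitscape.reads import FrequencyTable, REPLICATES, TIMEPOINTS

DEFAULT_S02_GRID = np.round(np.arange(0.0, 1.2 + 1e-9, 0.01), 10)
DEFAULT_K_GRID = np.round(np.arange(1.0, 14.0 + 1e-9, 0.1), 10)
DEFAULT_S_GRID = np.arange(-16.0, 3.0 + 1e-9, 0.1)
CALIBRATION_F0_THRESHOLD = 25e-6


@dataclass
class SegmentCalibration:
    """Segment-wide nuisance parameters (s̄_01 = 0 and t1 = 1 by convention)."""

    s02: float
    k: float
    objective: float
    n_genotypes: int = 0
    objective_surface: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# weighted exponential-fit objective, profiled over f0
# ---------------------------------------------------------------------------

def _eval_objective(F, W, s, s02: float, k: float):
    """Objective and optimal f0 at fitness ``s`` (f0 profiled out analytically).

    F, W are (..., 3) arrays of frequencies and weights 1/sigma^2; ``s``
    broadcasts against their leading dimensions.  The model trajectory is
    f0 * (1, exp(s), exp((s - s02)·k)); for fixed s the objective is
    quadratic in f0, giving the closed-form optimum.
    """
    s = np.asarray(s, float)
    a1 = np.exp(s)
    a2 = np.exp((s - s02) * k)
    A = np.stack([np.ones_like(a1), a1, a2], axis=-1)
    den = (W * A * A).sum(axis=-1)
    f0 = (W * F * A).sum(axis=-1) / den
    resid = F - f0[..., None] * A
    return (W * resid * resid).sum(axis=-1), f0


def _refine_ternary(F, W, lo, hi, s02, k, iters: int = 70):
    """Vectorised ternary search of the profiled objective on [lo, hi]."""
    for _ in range(iters):
        third = (hi - lo) / 3.0
        m1 = lo + third
        m2 = hi - third
        o1, _ = _eval_objective(F, W, m1, s02, k)
        o2, _ = _eval_objective(F, W, m2, s02, k)
        left = o1 < o2
        hi = np.where(left, m2, hi)
        lo = np.where(left, lo, m1)
    return 0.5 * (lo + hi)


def _minimize_s(F, W, s02: float, k: float, s_grid=None, method: str = "ternary",
                iters: int = 70):
    """Per-genotype minimiser over s: coarse grid then local refinement.

    ``method`` selects the refinement: "ternary" (high precision, used for
    final per-genotype fits), "parabolic" (one extra evaluation, used inside
    the calibration grid where only summed objectives are compared) or
    "none".
    """
    if s_grid is None:
        s_grid = DEFAULT_S_GRID
    obj, _ = _eval_objective(F[:, None, :], W[:, None, :], s_grid[None, :], s02, k)
    idx = np.argmin(obj, axis=1)
    s_at = s_grid[idx]
    if method == "none":
        o_hat, f0_hat = _eval_objective(F, W, s_at, s02, k)
        return s_at, o_hat, f0_hat
    # second stage: dense local grid around the coarse argmin.  The t2 term
    # carries a factor k in the exponent, so at small relative errors the
    # objective valley is far narrower than any practical coarse step.
    step = s_grid[1] - s_grid[0]
    fine_offsets = np.linspace(-1.2 * step, 1.2 * step, 49)
    obj_f, _ = _eval_objective(
        F[:, None, :], W[:, None, :], s_at[:, None] + fine_offsets[None, :], s02, k
    )
    jdx = np.argmin(obj_f, axis=1)
    s_fine = s_at + fine_offsets[jdx]
    fine_step = fine_offsets[1] - fine_offsets[0]
    if method == "parabolic":
        j0 = np.clip(jdx, 1, len(fine_offsets) - 2)
        rows = np.arange(len(jdx))
        y0, y1, y2 = obj_f[rows, j0 - 1], obj_f[rows, j0], obj_f[rows, j0 + 1]
        denom = y0 - 2 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = np.where(denom > 0, 0.5 * (y0 - y2) / denom * fine_step, 0.0)
        s_hat = s_at + fine_offsets[j0] + np.clip(shift, -fine_step, fine_step)
    elif method == "ternary":
        s_hat = _refine_ternary(
            F, W, s_fine - fine_step, s_fine + fine_step, s02, k, iters=iters
        )
    else:
        raise ValueError(f"unknown refinement method {method!r}")
    # fall back to the best grid value if refinement did not improve
    s_at = s_fine
    o_hat, f0_hat = _eval_objective(F, W, s_hat, s02, k)
    # keep the grid point if refinement did not help (degenerate objectives)
    o_grid, f0_grid = _eval_objective(F, W, s_at, s02, k)
    worse = o_grid < o_hat
    s_hat = np.where(worse, s_at, s_hat)
    o_hat = np.where(worse, o_grid, o_hat)
    f0_hat = np.where(worse, f0_grid, f0_hat)
    return s_hat, o_hat, f0_hat


# ---------------------------------------------------------------------------
# segment calibration
# ---------------------------------------------------------------------------

def calibrate_segment(
    ft: FrequencyTable,
    f0_threshold: float = CALIBRATION_F0_THRESHOLD,
    s02_grid: np.ndarray | None = None,
    k_grid: np.ndarray | None = None,
    s_grid: np.ndarray | None = None,
    max_genotypes: int = 300,
    min_genotypes: int = 1,
    keep_surface: bool = False,
) -> SegmentCalibration:
    """Exhaustive grid fit of (s̄_02, k) on high-frequency genotypes.

    Calibration genotypes are those with consensus t0 frequency above
    ``f0_threshold`` (~500-1000 reads per replicate at typical depths); the
    ``max_genotypes`` most frequent are used.  For every grid point the
    summed per-genotype minimum of the weighted objective is computed; the
    grid point with the minimal sum wins, ties resolved to the lowest s̄_02,
    then the lowest k.
    """
    if ft.variance is None:
        raise ValueError("attach a noise model before calibration")
    s02_grid = DEFAULT_S02_GRID if s02_grid is None else np.asarray(s02_grid, float)
    k_grid = DEFAULT_K_GRID if k_grid is None else np.asarray(k_grid, float)
    if s_grid is None:
        # calibration genotypes are high-frequency, hence never extreme
        # dropouts; a narrower, coarser inner grid (plus refinement) suffices
        s_grid = np.arange(-10.0, 2.01, 0.2)

    sel = ft.consensus[ft.consensus[0] > f0_threshold]
    if len(sel) < min_genotypes or sel.empty:
        raise ValueError(
            f"only {len(sel)} genotypes above the t0 frequency threshold"
        )
    if len(sel) > max_genotypes:
        sel = sel.nlargest(max_genotypes, 0)
    F = sel[list(TIMEPOINTS)].to_numpy()
    W = 1.0 / ft.variance.loc[sel.index, list(TIMEPOINTS)].to_numpy()

    best = None
    surface = np.empty((len(s02_grid), len(k_grid))) if keep_surface else None
    for i, s02 in enumerate(s02_grid):
        for j, k in enumerate(k_grid):
            _, obj, _ = _minimize_s(F, W, s02, k, s_grid=s_grid, method="parabolic")
            total = float(obj.sum())
            if surface is not None:
                surface[i, j] = total
            if best is None or total < best[0]:
                best = (total, s02, k)
    total, s02, k = best
    surface_df = (
        pd.DataFrame(surface, index=s02_grid, columns=k_grid)
        if surface is not None
        else None
    )
    return SegmentCalibration(
        s02=float(s02), k=float(k), objective=total,
        n_genotypes=len(sel), objective_surface=surface_df,
    )


# ---------------------------------------------------------------------------
# per-genotype fits
# ---------------------------------------------------------------------------

@dataclass
class FitnessEstimate:
    genotype: str
    s: float
    f0: float
    s_std: float | None
    is_boundary: bool = False
    s_scaled: float | None = None


def fit_genotypes(
    F: np.ndarray,
    sigma2: np.ndarray,
    calib: SegmentCalibration,
    s_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-genotype fit: returns (s, f0, s_std).

    ``F`` and ``sigma2`` are (G, 3) arrays of consensus frequencies and
    variances.  Standard errors come from the local curvature of the
    profiled objective: s_std = sqrt(2 / d2obj/ds2).
    """
    F = np.asarray(F, float)
    sigma2 = np.asarray(sigma2, float)
    if np.any(F[:, 0] <= 0):
        raise ValueError("fit requires f_t0 > 0 (boundary/dropped patterns go elsewhere)")
    if np.any(sigma2 <= 0):
        raise ValueError("variances must be positive")
    W = 1.0 / sigma2
    s_hat, _, f0_hat = _minimize_s(F, W, calib.s02, calib.k, s_grid=s_grid)
    h = 1e-3
    o_mid, _ = _eval_objective(F, W, s_hat, calib.s02, calib.k)
    o_plus, _ = _eval_objective(F, W, s_hat + h, calib.s02, calib.k)
    o_minus, _ = _eval_objective(F, W, s_hat - h, calib.s02, calib.k)
    curv = (o_plus - 2.0 * o_mid + o_minus) / h**2
    with np.errstate(divide="ignore", invalid="ignore"):
        s_std = np.where(curv > 0, np.sqrt(2.0 / np.maximum(curv, 1e-300)), np.nan)
    return s_hat, f0_hat, s_std


def fit_genotype(f, sigma2, calib: SegmentCalibration, genotype: str = "") -> FitnessEstimate:
    """Fit a single frequency trajectory (f_t0, f_t1, f_t2)."""
    s, f0, s_std = fit_genotypes(
        np.asarray(f, float)[None, :], np.asarray(sigma2, float)[None, :], calib
    )
    return FitnessEstimate(genotype, float(s[0]), float(f0[0]), float(s_std[0]))


def boundary_fitness(f, depths_t1: Iterable[float]) -> float:
    """Upper fitness bound for dropout genotypes: log(1/max_i N_i^t1).

    Applies to the pattern f_t0 > 0, f_t1 = 0, f_t2 = 0 only, for which the
    exponential fit has no information beyond "below one read at t1".
    """
    f = np.asarray(f, float)
    if not (f[0] > 0 and f[1] == 0 and f[2] == 0):
        raise ValueError("boundary fitness applies to the (f0>0, 0, 0) dropout pattern")
    return float(np.log(1.0 / max(depths_t1)))


def estimate_fitness(
    ft: FrequencyTable, calib: SegmentCalibration
) -> pd.DataFrame:
    """Fit every genotype of a frequency table; returns a per-genotype frame.

    Columns: s, f0, s_std, is_boundary.  Dropout genotypes get the boundary
    bound with no standard error.
    """
    if ft.variance is None:
        raise ValueError("attach a noise model before fitting")
    F = ft.consensus[list(TIMEPOINTS)].to_numpy()
    V = ft.variance[list(TIMEPOINTS)].to_numpy()
    dropout = (F[:, 0] > 0) & (F[:, 1] == 0) & (F[:, 2] == 0)
    fitted = ~dropout

    s = np.full(len(F), np.nan)
    f0 = np.full(len(F), np.nan)
    s_std = np.full(len(F), np.nan)
    if fitted.any():
        s[fitted], f0[fitted], s_std[fitted] = fit_genotypes(F[fitted], V[fitted], calib)
    if dropout.any():
        depths_t1 = [ft.depths[(r, 1)] for r in REPLICATES]
        s_bound = float(np.log(1.0 / max(depths_t1)))
        s[dropout] = s_bound
        f0[dropout] = F[dropout, 0]
    return pd.DataFrame(
        {"s": s, "f0": f0, "s_std": s_std, "is_boundary": dropout},
        index=ft.consensus.index,
    )


# ---------------------------------------------------------------------------
# rescaling and synonymous-based FDR
# ---------------------------------------------------------------------------

@dataclass
class RescaleTransform:
    zero_anchor: float  # 95th percentile of nonsense fitness -> 0
    one_anchor: float   # mode of the extant fitness distribution -> 1

    def __call__(self, s):
        scaled = (np.asarray(s, float) - self.zero_anchor) / (
            self.one_anchor - self.zero_anchor
        )
        return np.maximum(scaled, 0.0)


def distribution_mode(values: np.ndarray, bin_width: float = 0.01) -> float:
    """Peak of a fixed-bin-width histogram (first maximal bin on ties)."""
    values = np.asarray(values, float)
    lo, hi = values.min(), values.max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        return float(lo)
    counts, edges = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def rescale_fitness(
    s: pd.Series,
    nonsense: pd.Index | np.ndarray,
    extant: pd.Index | np.ndarray,
    bin_width: float = 0.01,
    min_anchor_genotypes: int = 50,
) -> tuple[pd.Series, RescaleTransform]:
    """Affine rescale: nonsense 95th percentile -> 0, extant mode -> 1.

    Nonsense (premature-stop) genotypes anchor lethality; the local maximum
    of the extant-genotype fitness distribution anchors neutrality.  Values
    below 0 after the map are clipped to 0.
    """
    s_nonsense = s.loc[nonsense].dropna()
    s_extant = s.loc[extant].dropna()
    if len(s_nonsense) < min_anchor_genotypes or len(s_extant) < min_anchor_genotypes:
        raise ValueError("need >= 50 nonsense and >= 50 extant genotypes to rescale")
    z0 = float(np.percentile(s_nonsense, 95))
    # the neutral peak: lethal extant genotypes overlap the nonsense
    # distribution, so the anchor is the mode of the extant fitness values
    # lying above the lethal anchor
    upper = s_extant[s_extant > z0]
    if len(upper) < min_anchor_genotypes:
        raise ValueError("degenerate distributions: no extant mass above the nonsense anchor")
    z1 = distribution_mode(upper.to_numpy(), bin_width)
    if z1 <= z0:
        raise ValueError("degenerate distributions: extant mode not above nonsense anchor")
    tr = RescaleTransform(z0, z1)
    return pd.Series(tr(s.to_numpy()), index=s.index), tr


@dataclass
class SynonymousFDR:
    false_unfit_rate: dict[int, float]
    false_fit_rate: dict[int, float]
    weights: dict[int, float]
    n_cases: dict[int, int] = field(default_factory=dict)

    @property
    def weighted_false_unfit(self) -> float:
        return _weighted(self.false_unfit_rate, self.weights)

    @property
    def weighted_false_fit(self) -> float:
        return _weighted(self.false_fit_rate, self.weights)


def _weighted(rates: Mapping[int, float], weights: Mapping[int, float]) -> float:
    num = sum(weights[n] * r for n, r in rates.items())
    den = sum(weights[n] for n in rates)
    return num / den if den else float("nan")


def classify_fitness_difference(diff, threshold: float = 0.4) -> np.ndarray:
    """-1 for false-unfit (diff < -threshold), +1 for false-fit (diff > threshold).

    Strict inequalities: a difference exactly at the threshold is neutral.
    """
    diff = np.asarray(diff, float)
    return np.where(diff < -threshold, -1, np.where(diff > threshold, 1, 0))


def synonymous_fdr(
    nt_ft: FrequencyTable,
    translations: Mapping[str, str],
    aa_scaled: pd.Series,
    calib: SegmentCalibration,
    transform: RescaleTransform,
    n_values: Iterable[int] = range(1, 11),
    threshold: float = 0.4,
    n_draws: int = 5,
    rng: np.random.Generator | None = None,
) -> SynonymousFDR:
    """False-fit / false-unfit rates from synonymous-subset refits.

    For each n, every amino-acid genotype with more than n synonymous
    nucleotide variants contributes up to ``n_draws`` random n-subsets:
    subset frequencies and variances are summed and refit, and the rescaled
    difference from the full amino-acid fitness is thresholded at +-0.4
    (strict inequalities).  Per-n rates are averaged with weights equal to
    the fraction of amino-acid genotypes having exactly n synonymous
    variants.
    """
    if nt_ft.variance is None:
        raise ValueError("attach a noise model to the nucleotide table first")
    rng = rng or np.random.default_rng()
    aa_of = pd.Series({g: translations[g] for g in nt_ft.consensus.index
                       if g in translations})
    by_aa: dict[str, list[str]] = {}
    for nt_g, aa_g in aa_of.items():
        if aa_g in aa_scaled.index:
            by_aa.setdefault(aa_g, []).append(nt_g)
    syn_counts = pd.Series({a: len(v) for a, v in by_aa.items()})
    weights = {
        n: float((syn_counts == n).mean()) for n in n_values
    }

    false_unfit: dict[int, float] = {}
    false_fit: dict[int, float] = {}
    n_cases: dict[int, int] = {}
    for n in n_values:
        eligible = [a for a, v in by_aa.items() if len(v) > n]
        if not eligible:
            continue
        F_rows, V_rows, targets = [], [], []
        for a in eligible:
            for _ in range(n_draws):
                subset = rng.choice(by_aa[a], size=n, replace=False)
                F_rows.append(nt_ft.consensus.loc[subset].sum(axis=0).to_numpy())
                V_rows.append(nt_ft.variance.loc[subset].sum(axis=0).to_numpy())
                targets.append(aa_scaled[a])
        F = np.array(F_rows)
        V = np.array(V_rows)
        # dropout subsets have no exponential fit (they would need the
        # boundary bound, which is not comparable to a fitted value)
        ok = (F[:, 0] > 0) & ~((F[:, 1] == 0) & (F[:, 2] == 0))
        if not ok.any():
            continue
        s_hat, _, _ = fit_genotypes(F[ok], V[ok], calib)
        diff = transform(s_hat) - np.asarray(targets)[ok]
        calls = classify_fitness_difference(diff, threshold)
        false_unfit[n] = float(np.mean(calls == -1))
        false_fit[n] = float(np.mean(calls == 1))
        n_cases[n] = int(ok.sum())
    return SynonymousFDR(false_unfit, false_fit, weights, n_cases)
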