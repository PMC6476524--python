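"""End-to-end convenience: simulate a segment and recover its fitness landscape.

Ties the stages together the way an analysis of a real segment would run:
read counts -> filtered nucleotide frequencies -> replicate noise model ->
amino-acid merge -> segment calibration -> per-genotype fitness -> rescaling.
The simulated ground truth rides along so recovery can be quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fitscape.codons import STOP
from fitscape.fitness import (
    RescaleTransform,
    SegmentCalibration,
    calibrate_segment,
    estimate_fitness,
    rescale_fitness,
)
from fitscape.landscape import GroundTruthLandscape, assign_true_fitness
from fitscape.library import SegmentLibrary
from fitscape.noise import NoiseModel
from fitscape.reads import (
    FrequencyTable,
    ReadCountTable,
    compute_frequencies,
    merge_amino_acid,
)
from fitscape.simulate import CompetitionParams, simulate_competition


@dataclass
class SegmentResult:
    library: SegmentLibrary
    true_fitness: dict[str, float]
    read_counts: ReadCountTable
    nt_table: FrequencyTable
    aa_table: FrequencyTable
    noise_model: NoiseModel
    calibration: SegmentCalibration
    estimates: pd.DataFrame  # s, f0, s_std, is_boundary, s_scaled, true_fitness
    transform: RescaleTransform

    def recovery_pearson_r(self, include_boundary: bool = True) -> float:
        """Pearson correlation between true and estimated rescaled fitness."""
        df = self.estimates.dropna(subset=["s_scaled", "true_fitness"])
        if not include_boundary:
            df = df[~df.is_boundary]
        return float(np.corrcoef(df.true_fitness, df.s_scaled)[0, 1])


def run_simulated_segment(
    lib: SegmentLibrary,
    landscape: GroundTruthLandscape,
    params: CompetitionParams,
    bin_size: int = 500,
    calibration_kwargs: dict | None = None,
) -> SegmentResult:
    """Simulate one bulk competition and run the full estimation chain on it.

    ``bin_size`` is the noise-model bin occupancy; the default of 500 suits
    simulated segments of a few thousand genotypes (the production default
    of 5000 genotypes per bin assumes library-scale data).
    """
    true_fitness = assign_true_fitness(lib, landscape)
    rct = simulate_competition(lib, true_fitness, params)

    nt_ft = compute_frequencies(rct)
    noise = NoiseModel.from_frequency_table(nt_ft, bin_size=bin_size)
    nt_ft.attach_variance(noise)

    translations = {g: lib.aa_of(g) for g in nt_ft.genotypes}
    aa_ft = merge_amino_acid(nt_ft, translations)

    calib = calibrate_segment(aa_ft, **(calibration_kwargs or {}))
    est = estimate_fitness(aa_ft, calib)

    nonsense = est.index[[STOP in g for g in est.index]]
    extant_states = {s: set(v) for s, v in lib.states_per_site.items()}
    extant = est.index[
        [
            STOP not in g
            and all(a in extant_states[s] for a, s in zip(g, lib.sites))
            for g in est.index
        ]
    ]
    scaled, transform = rescale_fitness(est.s, nonsense, extant)
    est = est.assign(
        s_scaled=scaled,
        true_fitness=pd.Series({g: true_fitness.get(g) for g in est.index}),
        is_nonsense=[STOP in g for g in est.index],
        is_extant=[g in set(extant) for g in est.index],
    )
    return SegmentResult(
        library=lib,
        true_fitness=true_fitness,
        read_counts=rct,
        nt_table=nt_ft,
        aa_table=aa_ft,
        noise_model=noise,
        calibration=calib,
        estimates=est,
        transform=transform,
    )


def noisy_fitness_table(
    genotypes,
    landscape: GroundTruthLandscape,
    sites: list[int],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Measured-like rescaled fitness: planted value plus Gaussian noise, clipped at 0.

    A fast stand-in for the full read-level pipeline when only a fitness
    table is needed (epistasis, potential-model and topology analyses).
    """
    rng = rng or np.random.default_rng()
    truth = np.array([landscape.fitness(g, sites) for g in genotypes])
    if noise_sd > 0:
        truth = truth + rng.normal(0.0, noise_sd, size=len(truth))
    return pd.Series(np.maximum(truth, 0.0), index=list(genotypes))
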