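"""Ground-truthed synthetic spectra and labeled feature sets.

Everything is driven by a seeded numpy Generator, so identical configs give
identical outputs.  Spectra carry planted averagine envelopes with
multiplicative log-normal intensity noise, ppm m/z jitter, Bernoulli peak
dropout and a uniform noise-peak floor; feature sets draw from documented
parametric distributions with labels from a logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isotope import averagine_distribution
from .msio import Spectrum
from .scoring import FeatureVector, WeightSet

__all__ = [
    "SimulationConfig",
    "PlantedIon",
    "GroundTruth",
    "SimulatedMatch",
    "simulate_spectrum",
    "simulate_feature_set",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_ions: int = 10
    mass_range: tuple[float, float] = (1000.0, 8000.0)
    charge_range: tuple[int, int] = (1, 10)
    base_intensity_range: tuple[float, float] = (1e3, 1e5)  # log-uniform
    noise_sigma: float = 0.2        # sigma of log-normal multiplicative noise
    jitter_ppm: float = 5.0
    dropout: float = 0.1
    n_noise_peaks: int = 200
    noise_intensity_range: tuple[float, float] = (1.0, 500.0)
    noise_mz_range: tuple[float, float] = (200.0, 2000.0)
    prune: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ions < 0 or self.n_noise_peaks < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if self.mass_range[0] > self.mass_range[1] or self.charge_range[0] > self.charge_range[1]:
            raise ValueError("empty range")


@dataclass(frozen=True)
class PlantedIon:
    monoisotopic_mass: float
    charge: int
    mz: np.ndarray           # true (pre-jitter) peak positions
    intensity: np.ndarray    # true (pre-noise) peak intensities
    dropped: np.ndarray      # per-peak dropout flags


@dataclass(frozen=True)
class GroundTruth:
    ions: tuple[PlantedIon, ...]

    @property
    def masses(self) -> np.ndarray:
        return np.array([ion.monoisotopic_mass for ion in self.ions])


def simulate_spectrum(cfg: SimulationConfig) -> tuple[Spectrum, GroundTruth]:
    """Emit one centroided spectrum plus the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    all_mz: list[np.ndarray] = []
    all_int: list[np.ndarray] = []
    ions: list[PlantedIon] = []
    for _ in range(cfg.n_ions):
        mass = rng.uniform(*cfg.mass_range)
        z = int(rng.integers(cfg.charge_range[0], cfg.charge_range[1] + 1))
        dist = averagine_distribution(mass, z, cfg.prune)
        lo, hi = np.log(cfg.base_intensity_range[0]), np.log(cfg.base_intensity_range[1])
        base = np.exp(rng.uniform(lo, hi))
        true_int = dist.prob / dist.prob.max() * base
        # weak peaks drop out; the strongest almost never do
        rel = dist.prob / dist.prob.max()
        dropped = rng.random(len(dist)) < cfg.dropout * (1.0 - rel)
        noisy_int = true_int * np.exp(rng.normal(0.0, cfg.noise_sigma, len(dist)))
        jitter = rng.normal(0.0, cfg.jitter_ppm * 1e-6, len(dist))
        noisy_mz = dist.mz * (1.0 + jitter)
        keep = ~dropped
        all_mz.append(noisy_mz[keep])
        all_int.append(noisy_int[keep])
        ions.append(
            PlantedIon(
                monoisotopic_mass=dist.monoisotopic_mass,
                charge=z,
                mz=dist.mz.copy(),
                intensity=true_int,
                dropped=dropped,
            )
        )
    if cfg.n_noise_peaks:
        all_mz.append(rng.uniform(*cfg.noise_mz_range, cfg.n_noise_peaks))
        all_int.append(rng.uniform(*cfg.noise_intensity_range, cfg.n_noise_peaks))
    mz = np.concatenate(all_mz) if all_mz else np.empty(0)
    intensity = np.concatenate(all_int) if all_int else np.empty(0)
    spectrum = Spectrum(mz, intensity, identifier=f"sim-{cfg.seed}")
    return spectrum, GroundTruth(ions=tuple(ions))


@dataclass
class SimulatedMatch:
    """Minimal labeled-match stand-in: enough for fitting and FDR tables."""

    k: int
    features: FeatureVector
    label: str
    monoisotopic_mass: float = 0.0
    charge: int = 1


#: Default feature-distribution parameters for :func:`simulate_feature_set`.
#: d_x and d_y are half-normal; s, n, m are Poisson (m clipped to the counts
#: the candidate filters allow, and fixed at 0 for the 2-peak group).
FEATURE_SIM_PARAMS = {
    "dx_scale": 0.25,
    "dy_scale": 0.6,
    "s_lambda": 0.8,
    "n_lambda": 0.8,
    "m_lambda": 0.7,
}


def simulate_feature_set(
    weights: WeightSet,
    n_per_group: int,
    seed: int = 0,
    groups: tuple[int, ...] = (2, 3, 4, 5),
    params: dict | None = None,
) -> list[SimulatedMatch]:
    """Draw labeled feature vectors from a logistic model with given weights.

    For each group, features come from the documented distributions and the
    incorrect-label probability is the logistic of the group's linear score
    plus a centering intercept (chosen so classes are roughly balanced).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    p = dict(FEATURE_SIM_PARAMS)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    out: list[SimulatedMatch] = []
    for g in groups:
        n = n_per_group
        d_x = np.abs(rng.normal(0.0, p["dx_scale"], n))
        d_y = np.abs(rng.normal(0.0, p["dy_scale"], n))
        s = rng.poisson(p["s_lambda"], n)
        nn = rng.poisson(p["n_lambda"], n)
        if g == 2:
            m = np.zeros(n, dtype=int)
        else:
            m_cap = 1 if g == 3 else 2
            m = np.minimum(rng.poisson(p["m_lambda"], n), m_cap)
        w = np.array(weights[g])
        X = np.column_stack([d_x, d_y, s, nn] + ([] if g == 2 else [m]))
        linear = X @ w
        linear = linear - linear.mean()  # centering intercept
        prob_incorrect = 1.0 / (1.0 + np.exp(-linear))
        incorrect = rng.random(n) < prob_incorrect
        for i in range(n):
            out.append(
                SimulatedMatch(
                    k=g if g < 5 else 5,
                    features=FeatureVector(
                        d_x=float(d_x[i]), d_y=float(d_y[i]),
                        s=int(s[i]), n=int(nn[i]), m=int(m[i]),
                    ),
                    label="incorrect" if incorrect[i] else "correct",
                )
            )
    return out
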