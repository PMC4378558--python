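"""Averagine composition estimation and centroided isotopomer distributions.

A centroided theoretical isotopomer distribution collapses all isotopologues
with the same total neutron count onto a single stick peak.  Adjacent peaks
are therefore spaced by ``ISOTOPE_SPACING / z`` Th at charge state ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import (
    AVERAGE_ATOMIC_MASS,
    AVERAGINE_UNIT,
    AVERAGINE_UNIT_MASS,
    ISOTOPE_SPACING,
    ISOTOPES,
    PROTON_MASS,
)

__all__ = [
    "ElementalComposition",
    "TheoreticalDistribution",
    "EmptyDistributionError",
    "averagine_composition",
    "isotope_distribution",
    "align_to_base_peak",
]

_ELEMENT_ORDER = ("C", "H", "N", "O", "S")


class EmptyDistributionError(ValueError):
    """Raised when pruning removes every peak of a distribution."""


@dataclass(frozen=True)
class ElementalComposition:
    """Integer CHNOS composition, hashable so distributions can be cached."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for element, count in self.counts:
            if element not in ISOTOPES:
                raise ValueError(f"unsupported element {element!r}")
            if count < 0:
                raise ValueError(f"negative count for {element}")
        if self.n_atoms == 0:
            raise ValueError("composition must contain at least one atom")

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "ElementalComposition":
        items = tuple(
            (el, int(counts[el])) for el in _ELEMENT_ORDER if counts.get(el, 0)
        )
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(ISOTOPES[el][0][0] * c for el, c in self.counts)

    @property
    def average_mass(self) -> float:
        return sum(AVERAGE_ATOMIC_MASS[el] * c for el, c in self.counts)

    def __str__(self) -> str:
        return "".join(f"{el}{c}" for el, c in self.counts)


@dataclass(frozen=True)
class TheoreticalDistribution:
    """Centroided isotopomer distribution of one ion at one charge state.

    ``mz`` is strictly increasing with spacing ``ISOTOPE_SPACING / z``;
    ``prob`` sums to one.  ``first_index`` is the neutron-count offset of the
    first retained peak relative to the monoisotopic peak (nonzero when
    low-probability leading peaks were pruned).
    """

    z: int
    mz: np.ndarray
    prob: np.ndarray
    monoisotopic_mass: float
    first_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "prob", np.asarray(self.prob, dtype=float))
        if self.z < 1:
            raise ValueError("charge state must be >= 1")
        if len(self.mz) != len(self.prob) or len(self.mz) == 0:
            raise ValueError("mz and prob must be equal-length and nonempty")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def index_of_most_abundant(self) -> int:
        return int(np.argmax(self.prob))


def averagine_composition(mass: float) -> ElementalComposition:
    """Estimate a CHNOS composition for an ion of the given average mass.

    The averagine unit formula is scaled by ``mass / unit_mass``, every
    element count is rounded to the nearest integer, and the hydrogen count
    is then adjusted so the composition's average mass lands as close as
    possible to the target.  Deterministic.
    """
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    ratio = mass / AVERAGINE_UNIT_MASS
    counts = {el: int(round(ratio * frac)) for el, frac in AVERAGINE_UNIT.items()}
    non_h_mass = sum(
        AVERAGE_ATOMIC_MASS[el] * c for el, c in counts.items() if el != "H"
    )
    h = int(round((mass - non_h_mass) / AVERAGE_ATOMIC_MASS["H"]))
    counts["H"] = max(h, 0)
    if sum(counts.values()) == 0:
        counts["H"] = 1
    return ElementalComposition.from_dict(counts)


def _atom_distribution(element: str) -> np.ndarray:
    table = ISOTOPES[element]
    dist = np.zeros(max(table) + 1)
    for shift, (_, abundance) in table.items():
        dist[shift] = abundance
    return dist


@lru_cache(maxsize=4096)
def _element_power(element: str, n: int) -> tuple[float, ...]:
    """Neutron-count distribution of ``n`` atoms of one element.

    Exponentiation by squaring over convolution; tails below 1e-15 are
    trimmed to keep array sizes bounded for large compositions.
    """
    base = _atom_distribution(element)
    result = np.array([1.0])
    power = base
    while n:
        if n & 1:
            result = _trim(np.convolve(result, power))
        n >>= 1
        if n:
            power = _trim(np.convolve(power, power))
    return tuple(result)


def _trim(dist: np.ndarray, eps: float = 1e-15) -> np.ndarray:
    keep = np.nonzero(dist > eps)[0]
    if len(keep) == 0:
        return dist[:1]
    return dist[: keep[-1] + 1]


def isotope_distribution(
    comp: ElementalComposition, z: int, prune: float = 0.01
) -> TheoreticalDistribution:
    """Centroided isotopomer distribution of ``comp`` at charge ``z``.

    Isotopologues are aggregated by total neutron count (a convolution of
    per-element distributions).  Peaks with probability below ``prune`` are
    removed — restricted to the contiguous block around the most abundant
    peak so the spacing invariant holds — and the rest renormalized.
    """
    if z < 1:
        raise ValueError("charge state must be >= 1")
    if not 0 <= prune < 1:
        raise ValueError("prune threshold must be in [0, 1)")
    dist = np.array([1.0])
    for element, count in comp.counts:
        dist = _trim(np.convolve(dist, np.asarray(_element_power(element, count))))
    dist = dist / dist.sum()

    if prune > 0:
        above = dist >= prune
        if not above.any():
            raise EmptyDistributionError(
                f"prune threshold {prune} removes all peaks of {comp}"
            )
        top = int(np.argmax(dist))
        lo = top
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = top
        while hi < len(dist) - 1 and above[hi + 1]:
            hi += 1
    else:
        lo, hi = 0, len(dist) - 1

    prob = dist[lo : hi + 1]
    prob = prob / prob.sum()
    mono = comp.monoisotopic_mass
    indices = np.arange(lo, hi + 1)
    mz = (mono + indices * ISOTOPE_SPACING + z * PROTON_MASS) / z
    return TheoreticalDistribution(z=z, mz=mz, prob=prob, monoisotopic_mass=mono, first_index=lo)


def align_to_base_peak(
    dist: TheoreticalDistribution, base_mz: float, z: int | None = None
) -> TheoreticalDistribution:
    """Rigidly shift ``dist`` so its most abundant peak sits at ``base_mz``.

    The monoisotopic mass is recomputed from the base-peak position:
    ``(base_mz - j * spacing / z - proton) * z`` with ``j`` the neutron-count
    offset of the most abundant peak.  Spacings are preserved exactly.
    """
    if base_mz <= 0:
        raise ValueError("base m/z must be positive")
    if z is None:
        z = dist.z
    elif z != dist.z:
        raise ValueError(f"charge mismatch: distribution has z={dist.z}, got {z}")
    j = dist.index_of_most_abundant + dist.first_index
    shift = base_mz - dist.mz[dist.index_of_most_abundant]
    mono = (base_mz - j * ISOTOPE_SPACING / z - PROTON_MASS) * z
    return TheoreticalDistribution(
        z=z,
        mz=dist.mz + shift,
        prob=dist.prob,
        monoisotopic_mass=mono,
        first_index=dist.first_index,
    )


@lru_cache(maxsize=8192)
def _cached_averagine_distribution(
    counts: tuple[tuple[str, int], ...], z: int, prune: float
) -> TheoreticalDistribution:
    return isotope_distribution(ElementalComposition(counts), z, prune)


def averagine_distribution(mass: float, z: int, prune: float = 0.01) -> TheoreticalDistribution:
    """Averagine distribution for a given (approximate) mass, cached.

    Candidate enumeration evaluates thousands of nearby masses; rounding to
    the nearest integer composition makes the cache effective.
    """
    comp = averagine_composition(mass)
    return _cached_averagine_distribution(comp.counts, z, prune)
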