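"""Candidate envelope enumeration, matching, scaling and filtering.

Candidates are generated by anchoring an averagine distribution at every
(signal peak, charge state) pair, matching its peaks against the spectrum,
scaling the probabilities to the experimental intensities, and applying the
missing-peak and consecutive-run filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import H2O_MASS, ISOTOPE_SPACING, NH3_MASS, PROTON_MASS
from .isotope import TheoreticalDistribution, averagine_distribution
from .msio import Spectrum

__all__ = [
    "TheoreticalEnvelope",
    "ExperimentalEnvelope",
    "EnvelopeMatch",
    "estimate_noise_level",
    "match_peaks",
    "scale_theoretical",
    "passes_filters",
    "generate_candidates",
    "annotate_support",
]


@dataclass
class TheoreticalEnvelope:
    """Scaled theoretical peaks that survived sub-noise pruning."""

    mz: np.ndarray
    intensity: np.ndarray
    z: int
    monoisotopic_mass: float
    base_peak_mz: float

    @property
    def k(self) -> int:
        return len(self.mz)


@dataclass
class ExperimentalEnvelope:
    """Experimental counterparts of a theoretical envelope.

    Unmatched theoretical peaks get zero-intensity placeholders at the
    theoretical m/z; ``peak_index`` is -1 there, otherwise the index of the
    matched peak in the source spectrum.
    """

    mz: np.ndarray
    intensity: np.ndarray
    placeholder: np.ndarray
    peak_index: np.ndarray

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def missing_count(self) -> int:
        return int(self.placeholder.sum())


@dataclass
class EnvelopeMatch:
    """A theoretical envelope paired with its experimental envelope."""

    theoretical: TheoreticalEnvelope
    experimental: ExperimentalEnvelope
    supporting_count: int = 0
    neutral_loss_count: int = 0
    label: str | None = None  # "correct" / "incorrect" / None
    features: "object | None" = None
    score: float | None = None
    fdr: float | None = None

    @property
    def k(self) -> int:
        return self.theoretical.k

    @property
    def missing_count(self) -> int:
        return self.experimental.missing_count

    @property
    def monoisotopic_mass(self) -> float:
        return self.theoretical.monoisotopic_mass

    @property
    def charge(self) -> int:
        return self.theoretical.z


def estimate_noise_level(spectrum: Spectrum, n_bins: int = 100) -> float:
    """Noise intensity level: upper edge of the most populated intensity bin.

    Bins are equal-width between 0 and the median of the top-decile
    intensities (peaks above that cap are unambiguous signal and excluded
    from the histogram so they cannot crowd the top bin).  A peak is a
    signal peak iff its intensity is strictly above the returned level.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot estimate noise level of an empty spectrum")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    intensity = spectrum.intensity
    n_top = max(1, len(intensity) // 10)
    cap = float(np.median(np.sort(intensity)[-n_top:]))
    if cap <= 0:
        return 0.0
    inside = intensity[intensity <= cap]
    if len(inside) == 0:
        inside = intensity
        cap = float(intensity.max())
    counts, edges = np.histogram(inside, bins=n_bins, range=(0.0, cap))
    return float(edges[int(np.argmax(counts)) + 1])


def default_mz_tolerance(mz: float, tol_th: float = 0.02, tol_ppm: float = 15.0) -> float:
    """Matching tolerance at a given m/z: max of absolute and ppm terms."""
    return max(tol_th, tol_ppm * 1e-6 * mz)


def match_peaks(
    dist: TheoreticalDistribution,
    spectrum: Spectrum,
    tol: float | None = None,
    tol_ppm: float = 15.0,
    tol_th: float = 0.02,
) -> ExperimentalEnvelope:
    """Match each theoretical peak to the nearest spectrum peak within tolerance.

    ``tol`` is a fixed tolerance in Th; when None, ``max(tol_th, tol_ppm)``
    is evaluated per peak.  Nearest peak wins; exact distance ties go to the
    higher intensity.  Unmatched positions become zero-intensity placeholders.
    """
    k = len(dist)
    mz = np.empty(k)
    intensity = np.zeros(k)
    placeholder = np.ones(k, dtype=bool)
    peak_index = np.full(k, -1, dtype=int)
    smz, sint = spectrum.mz, spectrum.intensity
    for i, target in enumerate(dist.mz):
        limit = tol if tol is not None else default_mz_tolerance(target, tol_th=tol_th, tol_ppm=tol_ppm)
        pos = np.searchsorted(smz, target)
        best = -1
        best_dist = limit
        for j in (pos - 1, pos):
            if 0 <= j < len(smz):
                d = abs(smz[j] - target)
                if d < best_dist or (
                    d == best_dist and best >= 0 and sint[j] > sint[best]
                ):
                    best, best_dist = j, d
        if best >= 0 and best_dist <= limit:
            mz[i] = smz[best]
            intensity[i] = sint[best]
            placeholder[i] = False
            peak_index[i] = best
        else:
            mz[i] = target
    return ExperimentalEnvelope(mz, intensity, placeholder, peak_index)


def scale_theoretical(
    dist: TheoreticalDistribution,
    exp: ExperimentalEnvelope,
    noise: float,
) -> tuple[TheoreticalEnvelope, ExperimentalEnvelope] | None:
    """Scale probabilities to intensities and prune sub-noise peaks.

    The scale ratio makes the summed intensity of the three most probable
    theoretical peaks equal the summed intensity of their experimental
    counterparts (all peaks when fewer than three; placeholders contribute
    zero).  Scaled peaks not above the noise level are removed together with
    their experimental counterparts.  Returns None when the envelope is
    unmatchable (zero ratio) or fewer than two peaks survive.
    """
    if len(dist) != len(exp):
        raise ValueError("distribution and experimental envelope length mismatch")
    n_top = min(3, len(dist))
    top = np.argsort(dist.prob)[::-1][:n_top]
    denom = float(dist.prob[top].sum())
    numer = float(exp.intensity[top].sum())
    if numer <= 0:
        return None
    scaled = dist.prob * (numer / denom)
    keep = scaled > noise
    if keep.sum() < 2:
        return None
    theo = TheoreticalEnvelope(
        mz=dist.mz[keep],
        intensity=scaled[keep],
        z=dist.z,
        monoisotopic_mass=dist.monoisotopic_mass,
        base_peak_mz=float(dist.mz[dist.index_of_most_abundant]),
    )
    trimmed = ExperimentalEnvelope(
        mz=exp.mz[keep],
        intensity=exp.intensity[keep],
        placeholder=exp.placeholder[keep],
        peak_index=exp.peak_index[keep],
    )
    return theo, trimmed


def _longest_matched_run(placeholder: np.ndarray) -> int:
    best = run = 0
    for missing in placeholder:
        run = 0 if missing else run + 1
        best = max(best, run)
    return best


def passes_filters(match: EnvelopeMatch) -> bool:
    """Missing-peak and consecutive-run candidate filters.

    Rejects envelopes with >= 3 missing peaks; 3 theoretical peaks and 2
    missing; 2 theoretical peaks and 1 missing; or without a run of k - 3
    consecutively matched peaks.
    """
    k = match.k
    missing = match.missing_count
    if missing >= 3:
        return False
    if k == 3 and missing == 2:
        return False
    if k == 2 and missing == 1:
        return False
    if _longest_matched_run(match.experimental.placeholder) < k - 3:
        return False
    return True


def generate_candidates(
    spectrum: Spectrum,
    max_charge: int = 30,
    tol: float | None = None,
    tol_ppm: float = 15.0,
    tol_th: float = 0.02,
    noise: float | None = None,
    prune: float = 0.01,
) -> list[EnvelopeMatch]:
    """Enumerate filtered envelope matches over all signal peaks and charges.

    Every signal peak is tried as the base peak of an averagine envelope at
    every charge in ``1..max_charge``; matches that survive scaling and the
    candidate filters are returned.  Exact duplicates (same charge, same
    monoisotopic mass to 1e-4 Da) are collapsed.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    if len(spectrum) == 0:
        return []
    if noise is None:
        noise = estimate_noise_level(spectrum)
    signal = np.nonzero(spectrum.intensity > noise)[0]
    from .isotope import align_to_base_peak

    candidates: list[EnvelopeMatch] = []
    seen: set[tuple[int, int]] = set()
    for idx in signal:
        base_mz = float(spectrum.mz[idx])
        for z in range(1, max_charge + 1):
            approx_mass = (base_mz - PROTON_MASS) * z
            if approx_mass <= 0:
                continue
            dist = averagine_distribution(approx_mass, z, prune)
            aligned = align_to_base_peak(dist, base_mz)
            if aligned.monoisotopic_mass <= 0:
                continue
            exp = match_peaks(aligned, spectrum, tol=tol, tol_ppm=tol_ppm, tol_th=tol_th)
            scaled = scale_theoretical(aligned, exp, noise)
            if scaled is None:
                continue
            theo, trimmed = scaled
            match = EnvelopeMatch(theoretical=theo, experimental=trimmed)
            if not passes_filters(match):
                continue
            key = (z, int(round(theo.monoisotopic_mass * 1e4)))
            if key in seen:
                continue
            seen.add(key)
            candidates.append(match)
    return candidates


def annotate_support(
    candidates: list[EnvelopeMatch], mass_tol_ppm: float = 15.0
) -> list[EnvelopeMatch]:
    """Count supporting and neutral-loss envelopes for each candidate.

    A supporting envelope has the same monoisotopic mass (within the ppm
    tolerance, +-1 isotope spacing allowed) at a different charge state; a
    neutral-loss envelope sits lower by the mass of NH3 or H2O.
    """
    masses = np.array([c.monoisotopic_mass for c in candidates])
    charges = np.array([c.charge for c in candidates])
    order = np.argsort(masses)
    sorted_masses = masses[order]

    def count_near(target: float, tol: float, exclude: int | None, other_charge: int | None) -> int:
        lo = np.searchsorted(sorted_masses, target - tol, side="left")
        hi = np.searchsorted(sorted_masses, target + tol, side="right")
        n = 0
        for pos in range(lo, hi):
            j = int(order[pos])
            if exclude is not None and j == exclude:
                continue
            if other_charge is not None and charges[j] == other_charge:
                continue
            n += 1
        return n

    for i, cand in enumerate(candidates):
        mass = cand.monoisotopic_mass
        tol = mass_tol_ppm * 1e-6 * mass
        f_s = 0
        for shift in (-ISOTOPE_SPACING, 0.0, ISOTOPE_SPACING):
            f_s += count_near(mass + shift, tol, exclude=i, other_charge=cand.charge)
        f_n = 0
        for loss in (NH3_MASS, H2O_MASS):
            f_n += count_near(mass - loss, tol, exclude=i, other_charge=None)
        cand.supporting_count = f_s
        cand.neutral_loss_count = f_n
    return candidates
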