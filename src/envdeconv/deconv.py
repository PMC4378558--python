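"""End-to-end deconvolution: candidates -> features -> score/FDR -> mass list.

The pipeline ranks filtered candidates by (local FDR, raw score), selects a
non-redundant subset greedily, merges cross-charge duplicates, and reports a
monoisotopic mass list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ISOTOPE_SPACING, MEAN_RESIDUE_AVG_MASS
from .detect import EnvelopeMatch, annotate_support, estimate_noise_level, generate_candidates
from .msio import Spectrum
from .scoring import FdrTable, WeightSet, compute_features, l_score, local_fdr

__all__ = [
    "DeconvParams",
    "MassEntry",
    "DeconvResult",
    "estimate_report_count",
    "select_envelopes",
    "deconvolute",
]

log = logging.getLogger(__name__)


@dataclass
class DeconvParams:
    max_charge: int = 30
    mz_tol_th: float = 0.02
    mz_tol_ppm: float = 15.0
    support_ppm: float = 15.0
    merge_ppm: float = 15.0
    prune: float = 0.01
    noise_bins: int = 100
    max_envelopes: int | None = None  # None: estimate from precursor mass
    fdr_ceiling: float | None = None
    weights: WeightSet | None = None
    fdr_table: FdrTable | None = None

    def resolved_weights(self) -> WeightSet:
        return self.weights if self.weights is not None else WeightSet.default()

    def resolved_fdr_table(self) -> FdrTable:
        return self.fdr_table if self.fdr_table is not None else FdrTable.default()


@dataclass
class MassEntry:
    mass: float
    charge: int
    intensity: float
    score: float
    fdr: float | None


@dataclass
class DeconvResult:
    identifier: str
    entries: list[MassEntry] = field(default_factory=list)
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    precursor_mass: float | None = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return np.array([e.mass for e in self.entries])


def estimate_report_count(precursor_mass: float, m_avg: float = MEAN_RESIDUE_AVG_MASS) -> int:
    """Report-count estimate 2(L - 1) with protein length L = ceil(M / m_avg)."""
    if precursor_mass <= 0:
        raise ValueError("precursor mass must be positive")
    length = math.ceil(precursor_mass / m_avg)
    return max(2 * (length - 1), 0)


def _sort_key(match: EnvelopeMatch):
    fdr = match.fdr if match.fdr is not None else 0.0
    return (fdr, match.score, -match.theoretical.intensity.sum(), match.monoisotopic_mass)


def _same_mass(m1: float, m2: float, ppm: float) -> bool:
    tol = ppm * 1e-6 * max(m1, m2)
    diff = abs(m1 - m2)
    return min(diff, abs(diff - ISOTOPE_SPACING)) <= tol


def select_envelopes(candidates: list[EnvelopeMatch], x: int) -> list[EnvelopeMatch]:
    """Greedy selection in (FDR, score) order with a shared-peak veto.

    A candidate is skipped when at least half of its non-placeholder
    experimental peaks are already claimed by an accepted candidate of a
    different monoisotopic mass.  At most ``x`` candidates are accepted.
    """
    if x <= 0:
        return []
    accepted: list[EnvelopeMatch] = []
    accepted_masses: list[float] = []
    claimed: dict[int, float] = {}  # spectrum peak index -> accepted mass
    n_distinct = 0
    for cand in sorted(candidates, key=_sort_key):
        indices = [int(i) for i in cand.experimental.peak_index if i >= 0]
        if indices:
            conflicts = sum(
                1
                for i in indices
                if i in claimed and not _same_mass(claimed[i], cand.monoisotopic_mass, 15.0)
            )
            if conflicts * 2 >= len(indices):
                continue
        # +-1-isotope variants of an accepted mass merge downstream and do
        # not consume the report budget
        duplicate = any(_same_mass(m, cand.monoisotopic_mass, 15.0) for m in accepted_masses)
        if not duplicate:
            if n_distinct >= x:
                continue
            n_distinct += 1
            accepted_masses.append(cand.monoisotopic_mass)
        accepted.append(cand)
        for i in indices:
            claimed.setdefault(i, cand.monoisotopic_mass)
    return accepted


def _merge_entries(selected: list[EnvelopeMatch], merge_ppm: float) -> list[MassEntry]:
    """Merge selected envelopes that share a monoisotopic mass across charges.

    Matching tolerates ``merge_ppm`` ppm plus a +-1 isotope-spacing error;
    intensities (summed experimental, non-placeholder) add up and the best
    (lowest-FDR, then lowest-score) member defines mass/charge/score.
    """
    entries: list[MassEntry] = []
    members: list[list[EnvelopeMatch]] = []
    for cand in sorted(selected, key=_sort_key):
        intensity = float(cand.experimental.intensity.sum())
        placed = False
        for entry, group in zip(entries, members):
            if _same_mass(entry.mass, cand.monoisotopic_mass, merge_ppm):
                entry.intensity += intensity
                group.append(cand)
                placed = True
                break
        if not placed:
            entries.append(
                MassEntry(
                    mass=cand.monoisotopic_mass,
                    charge=cand.charge,
                    intensity=intensity,
                    score=cand.score,
                    fdr=cand.fdr,
                )
            )
            members.append([cand])
    return entries


def deconvolute(spectrum: Spectrum, params: DeconvParams | None = None) -> DeconvResult:
    """Deconvolute one centroided spectrum into a ranked monoisotopic mass list."""
    params = params or DeconvParams()
    result = DeconvResult(
        identifier=spectrum.identifier,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        precursor_mass=spectrum.precursor_mass,
    )
    if len(spectrum) == 0:
        log.warning("spectrum %s is empty; nothing to deconvolute", spectrum.identifier)
        return result

    weights = params.resolved_weights()
    table = params.resolved_fdr_table()
    noise = estimate_noise_level(spectrum, params.noise_bins)
    candidates = generate_candidates(
        spectrum,
        max_charge=params.max_charge,
        tol_ppm=params.mz_tol_ppm,
        tol_th=params.mz_tol_th,
        noise=noise,
        prune=params.prune,
    )
    annotate_support(candidates, mass_tol_ppm=params.support_ppm)
    for cand in candidates:
        cand.features = compute_features(cand)
        cand.score = l_score(cand.features, weights, cand.k)
        cand.fdr = local_fdr(cand.score, cand.k, table)

    if params.fdr_ceiling is not None:
        candidates = [c for c in candidates if c.fdr <= params.fdr_ceiling]

    if params.max_envelopes is not None:
        x = params.max_envelopes
    elif spectrum.precursor_mass:
        x = estimate_report_count(spectrum.precursor_mass)
    else:
        x = len(candidates)
    selected = select_envelopes(candidates, x)
    result.entries = _merge_entries(selected, params.merge_ppm)
    log.info(
        "spectrum %s: %d candidates, %d selected, %d reported masses",
        spectrum.identifier, len(candidates), len(selected), len(result.entries),
    )
    return result
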