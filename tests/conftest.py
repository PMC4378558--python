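"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from envdeconv.constants import ISOTOPES
from envdeconv.detect import EnvelopeMatch, ExperimentalEnvelope, TheoreticalEnvelope
from envdeconv.scoring import FdrTable, WeightSet


# ---------------------------------------------------------------------------
# independent oracle: brute-force isotopologue enumeration
#
# Enumerates, per element, every way of distributing n atoms over the
# element's isotopes (multinomial), then combines elements by accumulating
# neutron-count totals in a dict.  Deliberately avoids the convolution code
# path used by the implementation.

def _element_neutron_dist(element: str, n: int) -> dict[int, float]:
    isotopes = sorted(ISOTOPES[element].items())  # (shift, (mass, abundance))
    out: dict[int, float] = {}

    def recurse(idx: int, remaining: int, shift: int, prob: float, denom: int) -> None:
        if idx == len(isotopes) - 1:
            s, (_, ab) = isotopes[idx]
            coeff = math.factorial(n) // denom // math.factorial(remaining)
            total = shift + s * remaining
            out[total] = out.get(total, 0.0) + coeff * prob * ab**remaining
            return
        s, (_, ab) = isotopes[idx]
        for count in range(remaining + 1):
            recurse(
                idx + 1,
                remaining - count,
                shift + s * count,
                prob * ab**count,
                denom * math.factorial(count),
            )

    recurse(0, n, 0, 1.0, 1)
    return out


def brute_force_distribution(counts: dict[str, int]) -> np.ndarray:
    """Neutron-count probability vector by exhaustive multinomial enumeration."""
    total: dict[int, float] = {0: 1.0}
    for element, n in counts.items():
        if n == 0:
            continue
        element_dist = _element_neutron_dist(element, n)
        combined: dict[int, float] = {}
        for s1, p1 in total.items():
            for s2, p2 in element_dist.items():
                combined[s1 + s2] = combined.get(s1 + s2, 0.0) + p1 * p2
        total = combined
    size = max(total) + 1
    out = np.zeros(size)
    for shift, prob in total.items():
        out[shift] = prob
    return out / out.sum()


# ---------------------------------------------------------------------------
# match construction helpers


def make_match(
    theo_mz,
    theo_int,
    exp_mz=None,
    exp_int=None,
    placeholder=None,
    z: int = 1,
    mono: float = 1000.0,
    supporting: int = 0,
    neutral_loss: int = 0,
) -> EnvelopeMatch:
    theo_mz = np.asarray(theo_mz, dtype=float)
    theo_int = np.asarray(theo_int, dtype=float)
    exp_mz = theo_mz.copy() if exp_mz is None else np.asarray(exp_mz, dtype=float)
    exp_int = theo_int.copy() if exp_int is None else np.asarray(exp_int, dtype=float)
    if placeholder is None:
        placeholder = exp_int == 0
    placeholder = np.asarray(placeholder, dtype=bool)
    peak_index = np.where(placeholder, -1, np.arange(len(theo_mz)))
    theo = TheoreticalEnvelope(
        mz=theo_mz,
        intensity=theo_int,
        z=z,
        monoisotopic_mass=mono,
        base_peak_mz=float(theo_mz[np.argmax(theo_int)]),
    )
    exp = ExperimentalEnvelope(
        mz=exp_mz, intensity=exp_int, placeholder=placeholder, peak_index=peak_index
    )
    return EnvelopeMatch(
        theoretical=theo,
        experimental=exp,
        supporting_count=supporting,
        neutral_loss_count=neutral_loss,
    )


def match_from_pattern(pattern: str, k: int | None = None) -> EnvelopeMatch:
    """Build a match from a matched/missing pattern ('m' matched, '.' missing)."""
    k = len(pattern) if k is None else k
    assert len(pattern) == k
    placeholder = np.array([c == "." for c in pattern])
    theo_mz = 500.0 + np.arange(k) * 1.00235
    theo_int = np.linspace(100.0, 50.0, k)
    exp_int = np.where(placeholder, 0.0, theo_int)
    return make_match(theo_mz, theo_int, exp_int=exp_int, placeholder=placeholder)


@pytest.fixture(scope="session")
def default_weights() -> WeightSet:
    return WeightSet.default()


@pytest.fixture(scope="session")
def default_fdr_table() -> FdrTable:
    return FdrTable.default()
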