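"""Label generation, per-group weight fitting and local-FDR table building.

Envelope matches are labeled correct when their monoisotopic mass maps onto
a theoretical b/y fragment (optionally with H2O/NH3 neutral losses) of an
annotated proteoform within 15 ppm, allowing a +-1 isotope-spacing error.
Weights are fitted per peak-pair group by logistic regression with the
incorrect class coded as 1, so lower linear scores mean better matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .constants import H2O_MASS, ISOTOPE_SPACING, NH3_MASS, RESIDUE_MONO_MASS
from .scoring import FdrTable, WeightSet, group_of, l_score

__all__ = [
    "FragmentSet",
    "ION_TYPES",
    "theoretical_fragments",
    "label_matches",
    "fit_weights",
    "build_fdr_table",
    "write_labeled_tsv",
]

ION_TYPES = ("b", "y", "b-H2O", "b-NH3", "y-H2O", "y-NH3")

_LOSS = {"": 0.0, "H2O": H2O_MASS, "NH3": NH3_MASS}


@dataclass(frozen=True)
class FragmentSet:
    """Neutral monoisotopic fragment masses of one proteoform."""

    sequence: str
    ion_types: tuple[str, ...]
    masses: np.ndarray  # sorted ascending
    names: tuple[str, ...]  # parallel to masses, e.g. "b3-H2O"


def theoretical_fragments(sequence: str, ion_types: Iterable[str] = ("b", "y")) -> FragmentSet:
    """Neutral b/y fragment masses (with optional neutral losses).

    b fragments are prefix residue-mass sums; y fragments are suffix sums
    plus one water.  One mass per (ion type, cleavage site).
    """
    sequence = sequence.strip().upper()
    for residue in sequence:
        if residue not in RESIDUE_MONO_MASS:
            raise ValueError(f"unknown residue {residue!r}")
    ion_types = tuple(ion_types)
    for ion in ion_types:
        if ion not in ION_TYPES:
            raise ValueError(f"unknown ion type {ion!r}; expected one of {ION_TYPES}")
    residues = np.array([RESIDUE_MONO_MASS[r] for r in sequence])
    prefix = np.cumsum(residues)
    masses: list[float] = []
    names: list[str] = []
    n = len(sequence)
    for ion in ion_types:
        series, _, loss = ion.partition("-")
        shift = -_LOSS[loss] if loss else 0.0
        # cleavage sites 1 .. n-1
        for site in range(1, n):
            if series == "b":
                mass = prefix[site - 1] + shift
            else:
                mass = prefix[-1] - prefix[n - site - 1] + H2O_MASS + shift
            if mass > 0:
                masses.append(float(mass))
                names.append(f"{series}{site}" + (f"-{loss}" if loss else ""))
    order = np.argsort(masses)
    return FragmentSet(
        sequence=sequence,
        ion_types=ion_types,
        masses=np.array(masses)[order],
        names=tuple(names[i] for i in order),
    )


def label_matches(
    matches: Sequence,
    frags: FragmentSet,
    ppm_tol: float = 15.0,
    isotope_error: float = ISOTOPE_SPACING,
) -> Sequence:
    """Label each match correct iff its mass maps to a fragment mass.

    The mapping tolerates ``ppm_tol`` ppm of the fragment mass and an
    additional shift of 0 or +-``isotope_error`` Da.
    """
    fmasses = frags.masses
    for match in matches:
        mass = match.monoisotopic_mass
        hit = False
        for shift in (-isotope_error, 0.0, isotope_error):
            target = mass - shift
            pos = np.searchsorted(fmasses, target)
            for j in (pos - 1, pos):
                if 0 <= j < len(fmasses):
                    if abs(target - fmasses[j]) <= ppm_tol * 1e-6 * fmasses[j]:
                        hit = True
                        break
            if hit:
                break
        match.label = "correct" if hit else "incorrect"
    return matches


def _group_arrays(labeled: Sequence) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-group (feature matrix, incorrect-indicator vector)."""
    groups: dict[int, tuple[list, list]] = {}
    for match in labeled:
        if match.label not in ("correct", "incorrect"):
            raise ValueError("all matches must be labeled before fitting")
        if match.features is None:
            raise ValueError("all matches must carry feature vectors")
        g = group_of(match.k)
        x = match.features.as_array(include_missing=g != 2)
        rows, ys = groups.setdefault(g, ([], []))
        rows.append(x)
        ys.append(1.0 if match.label == "incorrect" else 0.0)
    return {g: (np.array(rows), np.array(ys)) for g, (rows, ys) in groups.items()}


def fit_weights(labeled: Sequence, C: float = 1e6) -> WeightSet:
    """Fit per-group logistic-regression weights (incorrect class = 1).

    Regularization is kept negligible (large ``C``) so planted weights are
    recovered essentially unbiased while separable data still converges.
    Every group must contain both classes.
    """
    groups = _group_arrays(labeled)
    missing_groups = [g for g in (2, 3, 4, 5) if g not in groups]
    if missing_groups:
        raise ValueError(f"no envelope matches in group(s) {missing_groups}")
    weights: dict[int, tuple[float, ...]] = {}
    for g, (X, y) in groups.items():
        if len(np.unique(y)) < 2:
            raise ValueError(f"group {g} contains a single class; cannot fit")
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=20000, tol=1e-8)
        model.fit(X, y)
        weights[g] = tuple(float(w) for w in model.coef_[0])
    return WeightSet(weights)


def build_fdr_table(labeled: Sequence, weights: WeightSet) -> FdrTable:
    """Bin raw scores per group and count correct/incorrect labels per bin."""
    counts: dict[int, dict[int, list[int]]] = {}
    for match in labeled:
        g = group_of(match.k)
        score = l_score(match.features, weights, match.k)
        b = FdrTable.bin_index(score)
        cell = counts.setdefault(g, {}).setdefault(b, [0, 0])
        cell[0 if match.label == "correct" else 1] += 1
    return FdrTable(
        {g: {b: (c, i) for b, (c, i) in table.items()} for g, table in counts.items()}
    )


def write_labeled_tsv(labeled: Sequence, path: str | Path) -> None:
    """One row per labeled match: features, k, label, mass, charge."""
    lines = ["d_x\td_y\ts\tn\tm\tk\tlabel\tmass\tcharge"]
    for match in labeled:
        fv = match.features
        lines.append(
            f"{fv.d_x:.6f}\t{fv.d_y:.6f}\t{fv.s}\t{fv.n}\t{fv.m}\t{match.k}\t"
            f"{match.label}\t{match.monoisotopic_mass:.5f}\t{match.charge}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
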