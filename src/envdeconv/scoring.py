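"""The five envelope-match features, the linear score, and comparison scorers.

The raw score is a per-group linear combination of the features (no
intercept); lower scores indicate more plausible envelope matches.  Raw
scores are converted to local FDRs through per-group lookup tables with a
fixed bin width of 0.02.  Dot-product and KL-divergence scorers are provided
for benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .detect import EnvelopeMatch

__all__ = [
    "FeatureVector",
    "WeightSet",
    "FdrTable",
    "FDR_BIN_WIDTH",
    "mz_distance",
    "intensity_distance",
    "compute_features",
    "l_score",
    "local_fdr",
    "dot_product_score",
    "kl_divergence",
]

#: Raw-score bin width of the local-FDR lookup tables.
FDR_BIN_WIDTH = 0.02

GROUPS = (2, 3, 4, 5)
FEATURE_NAMES = ("mz_distance", "intensity_distance", "supporting", "neutral_loss", "missing")


def group_of(k: int) -> int:
    """Peak-pair-count group: 2, 3, 4 or 5 (the latter meaning >= 5)."""
    if k < 2:
        raise ValueError(f"peak-pair count must be >= 2, got {k}")
    return min(k, 5)


@dataclass(frozen=True)
class FeatureVector:
    d_x: float  # m/z RMSD over non-placeholder pairs, Th
    d_y: float  # thresholded/penalized intensity RMS over all pairs
    s: int      # number of supporting envelopes
    n: int      # number of neutral-loss envelopes
    m: int      # number of missing (placeholder) peaks

    def as_array(self, include_missing: bool = True) -> np.ndarray:
        values = [self.d_x, self.d_y, self.s, self.n]
        if include_missing:
            values.append(self.m)
        return np.array(values, dtype=float)


class WeightSet:
    """Per-group linear weights for the five features.

    Group 2 carries four weights (the missing-peak feature is unused there);
    the other groups carry five.  Serializes to a whitespace-separated text
    table, one line per group.
    """

    def __init__(self, weights: dict[int, tuple[float, ...]]):
        if set(weights) != set(GROUPS):
            raise ValueError(f"weights must cover groups {GROUPS}")
        for g, w in weights.items():
            expected = 4 if g == 2 else 5
            if len(w) != expected:
                raise ValueError(f"group {g} needs {expected} weights, got {len(w)}")
        self.weights = {g: tuple(float(x) for x in w) for g, w in weights.items()}

    def __getitem__(self, group: int) -> tuple[float, ...]:
        return self.weights[group]

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightSet) and self.weights == other.weights

    @classmethod
    def default(cls) -> "WeightSet":
        """The shipped default weights (logistic regression on CID training data)."""
        with resources.files("envdeconv.data").joinpath("lscore_weights.txt").open() as fh:
            return cls._parse(fh.read())

    @classmethod
    def from_file(cls, path: str | Path) -> "WeightSet":
        return cls._parse(Path(path).read_text())

    @classmethod
    def _parse(cls, text: str) -> "WeightSet":
        weights: dict[int, tuple[float, ...]] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            group = 5 if fields[0] in ("5+", "5") else int(fields[0])
            values = tuple(float(f) for f in fields[1:] if f != "-")
            weights[group] = values
        return cls(weights)

    def to_file(self, path: str | Path) -> None:
        lines = ["# group  " + "  ".join(FEATURE_NAMES)]
        for g in GROUPS:
            name = "5+" if g == 5 else str(g)
            row = "  ".join(f"{w:.6g}" for w in self.weights[g])
            if g == 2:
                row += "  -"
            lines.append(f"{name}  {row}")
        Path(path).write_text("\n".join(lines) + "\n")


class FdrTable:
    """Per-group raw-score -> local-FDR lookup with 0.02-wide bins.

    Each bin stores (correct, incorrect) training counts; the FDR of a bin
    is incorrect / (correct + incorrect).  Scores falling in an empty bin
    inherit the nearest populated bin's FDR (ties toward the lower bin).
    """

    def __init__(
        self,
        counts: dict[int, dict[int, tuple[int, int]]],
        fdr: dict[int, dict[int, float]] | None = None,
    ):
        self.counts = {
            g: {int(b): (int(c), int(i)) for b, (c, i) in table.items()}
            for g, table in counts.items()
        }
        # optional smoothed per-bin FDR overriding the raw count ratio
        self.fdr = (
            {g: {int(b): float(v) for b, v in table.items()} for g, table in fdr.items()}
            if fdr
            else None
        )
        self._sorted_bins = {g: sorted(t) for g, t in self.counts.items()}

    @staticmethod
    def bin_index(score: float) -> int:
        return int(math.floor(score / FDR_BIN_WIDTH))

    def lookup(self, score: float, k: int) -> float:
        group = group_of(k)
        table = self.counts.get(group)
        if not table:
            raise ValueError(f"no FDR table for group {group}")
        idx = self.bin_index(score)
        if idx not in table:
            bins = self._sorted_bins[group]
            pos = np.searchsorted(bins, idx)
            options = [b for b in (bins[pos - 1] if pos > 0 else None,
                                   bins[pos] if pos < len(bins) else None)
                       if b is not None]
            idx = min(options, key=lambda b: (abs(b - idx), b))
        if self.fdr is not None:
            return self.fdr[group][idx]
        correct, incorrect = table[idx]
        return incorrect / (correct + incorrect)

    def isotonic(self) -> "FdrTable":
        """Smoothed copy: per-group FDR made non-decreasing in the raw score.

        Weighted isotonic regression of the per-bin count ratios (weights =
        bin occupancies).  Smoothing removes sampling noise so that ranking
        by local FDR agrees with ranking by raw score within a group.
        """
        from sklearn.isotonic import IsotonicRegression

        fdr: dict[int, dict[int, float]] = {}
        for g, table in self.counts.items():
            bins = sorted(table)
            raw = np.array([table[b][1] / sum(table[b]) for b in bins])
            weights = np.array([sum(table[b]) for b in bins], dtype=float)
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
            smoothed = iso.fit_transform(bins, raw, sample_weight=weights)
            fdr[g] = {b: float(v) for b, v in zip(bins, smoothed)}
        return FdrTable(self.counts, fdr=fdr)

    @classmethod
    def default(cls) -> "FdrTable":
        with resources.files("envdeconv.data").joinpath("lscore_fdr.txt").open() as fh:
            return cls._parse(fh.read())

    @classmethod
    def from_file(cls, path: str | Path) -> "FdrTable":
        return cls._parse(Path(path).read_text())

    @classmethod
    def _parse(cls, text: str) -> "FdrTable":
        counts: dict[int, dict[int, tuple[int, int]]] = {}
        fdr: dict[int, dict[int, float]] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            group = 5 if fields[0] in ("5+", "5") else int(fields[0])
            b = int(fields[1])
            counts.setdefault(group, {})[b] = (int(fields[2]), int(fields[3]))
            if len(fields) > 4:
                fdr.setdefault(group, {})[b] = float(fields[4])
        return cls(counts, fdr=fdr or None)

    def to_file(self, path: str | Path) -> None:
        lines = ["# group  bin_index  n_correct  n_incorrect  [smoothed_fdr]   (bin width 0.02)"]
        for g in sorted(self.counts):
            name = "5+" if g == 5 else str(g)
            for b in sorted(self.counts[g]):
                c, i = self.counts[g][b]
                row = f"{name}  {b}  {c}  {i}"
                if self.fdr is not None:
                    row += f"  {self.fdr[g][b]:.6f}"
                lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# features


def mz_distance(match: EnvelopeMatch) -> float:
    """RMSD of m/z errors over matched (non-placeholder) peak pairs."""
    real = ~match.experimental.placeholder
    if not real.any():
        raise ValueError("m/z distance undefined: all peak pairs are placeholders")
    err = match.theoretical.mz[real] - match.experimental.mz[real]
    return float(np.sqrt(np.mean(err * err)))


def intensity_distance(match: EnvelopeMatch, t: float = 0.5, c: float = 2.0) -> float:
    """Thresholded, asymmetrically penalized RMS of relative-intensity errors.

    Relative intensities divide by the highest theoretical peak intensity.
    Per pair, error e = r(experimental) - r(theoretical); the contribution is
    min(e, t) for e >= 0 and min(c * -e, c * t) otherwise.  Placeholder
    pairs enter with experimental intensity zero.
    """
    y_h = float(match.theoretical.intensity.max())
    if y_h <= 0:
        raise ValueError("theoretical envelope has no positive peak")
    e = match.experimental.intensity / y_h - match.theoretical.intensity / y_h
    d = np.where(e >= 0, np.minimum(e, t), np.minimum(c * -e, c * t))
    return float(np.sqrt(np.mean(d * d)))


def compute_features(match: EnvelopeMatch, t: float = 0.5, c: float = 2.0) -> FeatureVector:
    return FeatureVector(
        d_x=mz_distance(match),
        d_y=intensity_distance(match, t=t, c=c),
        s=match.supporting_count,
        n=match.neutral_loss_count,
        m=match.missing_count,
    )


def l_score(fv: FeatureVector, weights: WeightSet, k: int) -> float:
    """Linear combination of the features for the group of ``k``.

    Lower is better: the weights are oriented toward the incorrect class, so
    distances push the score up and supporting/neutral-loss counts pull it
    down.  Group 2 has no missing-peak term.
    """
    group = group_of(k)
    w = weights[group]
    score = w[0] * fv.d_x + w[1] * fv.d_y + w[2] * fv.s + w[3] * fv.n
    if group != 2:
        score += w[4] * fv.m
    return score


def local_fdr(score: float, k: int, table: FdrTable) -> float:
    return table.lookup(score, k)


# ---------------------------------------------------------------------------
# comparison scorers


def dot_product_score(match: EnvelopeMatch) -> float:
    """Cosine similarity of the two k-length intensity vectors."""
    y = match.theoretical.intensity
    y2 = match.experimental.intensity
    norm2 = float(np.linalg.norm(y2))
    if norm2 == 0:
        return 0.0
    return float(y @ y2 / (np.linalg.norm(y) * norm2))


def kl_divergence(match: EnvelopeMatch, pseudocount: float = 1e-6) -> float:
    """KL divergence of the experimental from the theoretical distribution.

    Both intensity vectors are normalized to probability distributions; a
    pseudocount of ``pseudocount`` times the vector's total intensity is
    added to every component first so zero experimental intensities stay
    finite.  An all-zero experimental envelope returns +inf.
    """
    y = match.theoretical.intensity.astype(float)
    y2 = match.experimental.intensity.astype(float)
    if y2.sum() == 0:
        return math.inf
    p = y + pseudocount * y.sum()
    q = y2 + pseudocount * y2.sum()
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))
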