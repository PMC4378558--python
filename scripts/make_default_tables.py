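"""Regenerate the shipped default local-FDR table.

The table is built from a large seeded synthetic labeled feature set scored
with the shipped default weights, so the pipeline has a sensible calibration
out of the box.  Run from the repository root:

    python scripts/make_default_tables.py
"""

from pathlib import Path

from envdeconv.scoring import WeightSet
from envdeconv.simulate import simulate_feature_set
from envdeconv.training import build_fdr_table

OUT = Path(__file__).resolve().parents[1] / "src" / "envdeconv" / "data" / "lscore_fdr.txt"


def main() -> None:
    weights = WeightSet.default()
    labeled = simulate_feature_set(weights, n_per_group=50000, seed=20140)
    # shipped smoothed so that within-group FDR ranking matches score ranking
    table = build_fdr_table(labeled, weights).isotonic()
    table.to_file(OUT)
    n_bins = sum(len(t) for t in table.counts.values())
    print(f"wrote {n_bins} bins over {len(table.counts)} groups -> {OUT}")


if __name__ == "__main__":
    main()
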