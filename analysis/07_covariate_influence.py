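#!/usr/bin/env python
"""Covariate influence across the seven indicator models.

Refits one minimum-Cp model per indicator on all data, aggregates the
rainfall lags and the two wind components, and scores each covariate by
summed |coefficients|, occurrence proportion and Total Score.  Writes the
influence table and the signed-coefficient heatmap matrix under results/.
"""

from pathlib import Path

from beachcast.influence import (
    coefficient_table,
    full_data_coefficients,
    heatmap_matrix,
    influence_scores,
    write_heatmap_csv,
)
from beachcast.pipeline import INFLUENCE_GROUPS
from beachcast.preprocess import ModelFrame

FRAMES = Path("results/frames")
OUT = Path("results")


def main() -> None:
    models = {}
    heat = {}
    for path in sorted(FRAMES.glob("*.csv")):
        frame = ModelFrame.from_csv(path)
        coefs = full_data_coefficients(frame)
        models[(frame.site, frame.indicator)] = coefs
        heat[frame.indicator] = coefs

    table = coefficient_table(models)
    groups = {g: m for g, m in INFLUENCE_GROUPS.items() if set(m) <= set(table.columns)}
    scores = influence_scores(table, groups=groups)
    scores.to_csv(OUT / "influence_table.csv")
    print("covariate influence (Total Score = summed |coef| + occurrence):")
    print(scores.round(3).to_string())

    matrix = heatmap_matrix(heat)
    write_heatmap_csv(matrix, OUT / "coefficient_heatmap.csv")
    print(f"\nheatmap matrix: {matrix.shape[0]} covariates x "
          f"{matrix.shape[1]} indicators (alphabetical covariate order)")


if __name__ == "__main__":
    main()
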