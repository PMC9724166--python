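#!/usr/bin/env python
"""Ten-fold cross-validation and the cross-model performance board.

Every indicator model is scored by SRMSEP and predictive R2 from
out-of-fold predictions; metrics are standardized by their cross-model
maxima and combined into Overall Performance.  Writes per-indicator CV
predictions and the board under results/.
"""

from pathlib import Path

import pandas as pd

from beachcast.evaluate import build_board, score_frame
from beachcast.preprocess import ModelFrame

FRAMES = Path("results/frames")
OUT = Path("results")
SEED = 20220601


def main() -> None:
    (OUT / "cv").mkdir(parents=True, exist_ok=True)
    rows = []
    for path in sorted(FRAMES.glob("*.csv")):
        frame = ModelFrame.from_csv(path)
        score = score_frame(frame, k=10, seed=SEED)
        score.pop("cv").table.to_csv(OUT / "cv" / f"{frame.indicator}.csv", index=False)
        rows.append(score)
    board = build_board(pd.DataFrame(rows)).sort_values(
        "overall_performance", ascending=False
    )
    board.to_csv(OUT / "performance_board.csv", index=False)
    print("performance board (best to worst):")
    print(board.round(3).to_string(index=False))
    best = board.iloc[0]
    print(f"\nbest model: {best['indicator']} "
          f"(R2pred {best['rpred2']:.2f}, SRMSEP {best['srmsep']:.2f}, "
          f"Overall Performance {best['overall_performance']:.2f})")


if __name__ == "__main__":
    main()
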