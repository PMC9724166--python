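#!/usr/bin/env python
"""Fit one LARS-lasso path per indicator and select the minimum-Cp model.

Writes the per-step path (coefficients, RSS, Cp) and the selected model for
each indicator under results/fits/.
"""

import json
from pathlib import Path

from beachcast.lars import lars_fit, select_min_cp
from beachcast.preprocess import ModelFrame

FRAMES = Path("results/frames")
OUT = Path("results/fits")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for path in sorted(FRAMES.glob("*.csv")):
        frame = ModelFrame.from_csv(path)
        lars = lars_fit(frame.X, frame.y)
        model = select_min_cp(lars)
        lars.to_frame().to_csv(OUT / f"{frame.indicator}_path.csv", index=False)
        (OUT / f"{frame.indicator}_selected.json").write_text(json.dumps({
            "intercept": model.intercept,
            "coefficients": {k: float(v) for k, v in model.coefficients.items()},
            "active_set": model.active_set,
            "selected_step": lars.selected_step,
        }, indent=1))
        step = lars.steps[lars.selected_step]
        print(f"{frame.indicator}: {len(lars.steps)} path steps, selected step "
              f"{lars.selected_step} (Cp {step.cp:.2f}), "
              f"{len(model.active_set)} active covariates")


if __name__ == "__main__":
    main()
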