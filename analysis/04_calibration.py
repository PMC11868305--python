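#!/usr/bin/env python
"""Monte-Carlo calibration of the pipeline's inference.

Two studies with known ground truth: (1) the size of the level x delay
interaction F-test under a null interaction (flat retention, level effect
preserved), at the experiment-1 geometry; (2) recovery error of the
retention slope b as participants per delay group double. Run sizes are
the package defaults (2000 null simulations; 200 studies per group size).
"""

import time
from pathlib import Path

import pandas as pd

from lopforget.calibration import interaction_type1_error, slope_recovery
from lopforget.design import EXP1_DESIGN

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    OUT.mkdir(exist_ok=True)

    t0 = time.time()
    res = interaction_type1_error(EXP1_DESIGN, n_sims=2000, seed=SEED)
    print(f"interaction type-I error under the null "
          f"({res['n_sims']} simulated studies, {time.time() - t0:.0f}s): "
          f"{res['rejection_rate']:.3f} (MC SE {res['mc_se']:.3f}, "
          f"nominal {res['alpha']})")
    pd.DataFrame([res]).to_csv(OUT / "calibration_type1.csv", index=False)

    t0 = time.time()
    rec = slope_recovery(participants_per_group=(15, 30, 60), n_studies=200,
                         seed=0)
    print(f"\nslope recovery, power law a=2.5 b=0.4 ({time.time() - t0:.0f}s):")
    print(rec.round(4).to_string(index=False))
    rec.round(6).to_csv(OUT / "calibration_recovery.csv", index=False)
    print("\nmedian |b_hat - b| shrinks with group size; the residual floor "
          "reflects the d' measurement bias at 10 targets per cell "
          "(see docs/methods.md)")


if __name__ == "__main__":
    main()
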