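#!/usr/bin/env python
"""Dereplicate the strain panel and score strain-caller recovery.

Runs the 20-sample panel experiment (uninfected / single / dual
infections at 25x, 0.2% error) through the full screen + iterate decision
chain and writes per-sample calls and summary precision/recall.
"""

import json
from pathlib import Path

import pandas as pd

from wolbshift import experiments

OUT = Path(__file__).resolve().parents[1] / "results" / "straincall"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = experiments.strain_recovery_experiment(seed=SEED)
    calls = pd.DataFrame(
        [
            {"sample": r["sample"], "truth": ",".join(r["truth"]),
             "called": ",".join(r["called"]), "status": r["status"]}
            for r in res["records"]
        ]
    )
    calls.to_csv(OUT / "panel_calls.tsv", sep="\t", index=False)
    summary = {"precision": res["precision"], "recall": res["recall"],
               "n_samples": res["n_samples"], "seed": SEED}
    (OUT / "recovery.json").write_text(json.dumps(summary, indent=2))
    print(f"strain assignment on {res['n_samples']} samples: "
          f"precision={res['precision']:.3f} recall={res['recall']:.3f}")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
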