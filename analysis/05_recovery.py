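#!/usr/bin/env python
"""Parameter- and model-recovery experiments (reduced replicate count).

Closes the simulate-fit loop: (a) parameter recovery for the punishment
model at 20 subjects x 300 trials over two seeds, reporting true-vs-
recovered correlations in transformed space, and (b) a one-replicate model
recovery run for the punishment and action-only generators.  The full
design sizes (40 subjects, 5 seeds) run in scripts/acceptance.py; this
driver uses smaller replicates so the whole analysis sequence stays quick.
Writes results/recovery_report.json and results/model_confusion.csv.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from prtlearn.io import _jsonable  # noqa: E402
from prtlearn.selection import (  # noqa: E402
    model_recovery_experiment,
    parameter_recovery_experiment,
    recovery_cohort_spec,
)

OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = recovery_cohort_spec("punishment", n_subjects=20)
    report = parameter_recovery_experiment(spec, seeds=(0, 1))
    with open(OUT / "recovery_report.json", "w") as fh:
        json.dump(_jsonable(report.to_dict()), fh, indent=2)
        fh.write("\n")
    print("parameter recovery (punishment, 20 subjects x 300 trials, 2 seeds)")
    print("mean true-vs-recovered r by parameter:")
    print(report.mean_correlations().round(3).to_string())

    specs = {g: recovery_cohort_spec(g, n_subjects=20)
             for g in ("punishment", "action_only")}
    confusion = model_recovery_experiment(specs, seeds=(0,))
    confusion.to_csv(OUT / "model_confusion.csv")
    print("\nmodel recovery (1 replicate per generator): iBIC winners")
    print(confusion.to_string())


if __name__ == "__main__":
    main()
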