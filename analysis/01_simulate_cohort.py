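#!/usr/bin/env python
"""Simulate the longitudinal study cohort.

Generates the synthetic stand-in for the study design: 19 completers, each
performing the 300-trial probabilistic reward task at three sessions (S0
smoking as usual, ABS2 after 48 h abstinence, ABS30 after 30 days), with
choices produced by punishment-model agents whose log punishment
sensitivity is raised by +0.5 at ABS30.  Writes the trial table, the true
generating parameters, and a manifest under results/cohort/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import prtlearn as pl  # noqa: E402
import prtlearn.io as pio  # noqa: E402
from prtlearn.selection import recovery_cohort_spec  # noqa: E402

OUT = ROOT / "results" / "cohort"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = recovery_cohort_spec(
        "punishment", n_subjects=19, sessions=("S0", "ABS2", "ABS30"),
        session_effects={"ABS30": {"beta_punishment": 0.5}}, seed=SEED,
    )
    cohort = pl.generate_cohort(spec)
    pio.write_trials(cohort.trials, OUT / "trials.csv")
    pio.write_params_table(cohort.truth, OUT / "true_params.csv")
    pio.write_manifest(OUT / "manifest.json", command="01_simulate",
                       cohort=spec, rich_stimulus=cohort.rich_stimulus)
    units = cohort.trials.groupby(["subject_id", "session"]).size()
    print(f"simulated {len(units)} subject-sessions of {units.iloc[0]} trials "
          f"({len(cohort.trials)} trials total) -> {OUT}")
    acc = cohort.trials.groupby("session")["correct"].mean()
    print("overall accuracy by session:")
    print(acc.round(3).to_string())


if __name__ == "__main__":
    main()
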