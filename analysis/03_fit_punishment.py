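#!/usr/bin/env python
"""Hierarchical fit of the punishment model to the simulated cohort.

Runs empirical-Bayes EM over all 57 subject-sessions with a shared group
prior, writes the per-session posterior-mode parameter table and the
fitted prior, and reports the session means of log punishment sensitivity
-- the quantity the longitudinal design is about.  Run 01 first.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import prtlearn.io as pio  # noqa: E402
from prtlearn.fitting import em_group_fit  # noqa: E402

OUT = ROOT / "results"
SEED = 0


def main() -> None:
    trials = pio.read_trials(OUT / "cohort" / "trials.csv")
    res = em_group_fit(trials, "punishment", seed=SEED)
    table = res.params_table()
    table.to_csv(OUT / "fit_params.csv", index=False)
    with open(OUT / "group_prior.json", "w") as fh:
        json.dump(res.prior.to_dict(), fh, indent=2)
        fh.write("\n")
    res.history.to_csv(OUT / "em_history.csv", index=False)
    print(f"EM converged in {len(res.history)} iterations "
          f"(final approx. marginal log-lik {res.history['approx_ml'].iloc[-1]:.1f})")
    bp = table[table["param"] == "beta_punishment"].pivot_table(
        index="subject_id", columns="session", values="transformed_value"
    )
    means = bp.mean().loc[["S0", "ABS2", "ABS30"]]
    print("recovered mean log(beta_punishment) by session:")
    print(means.round(3).to_string())
    diff = (bp["ABS30"] - bp["S0"]).mean()
    print(f"paired ABS30-S0 difference: {diff:+.3f} "
          "(the generating shift is +0.5; empirical-Bayes shrinkage "
          "attenuates but preserves its sign)")


if __name__ == "__main__":
    main()
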