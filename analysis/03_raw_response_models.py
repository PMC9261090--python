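"""Raw emotional responses: category models and symptom moderation.

Fits the three multilevel models (positivity, negativity, arousal on
stimulus category with maximal crossed random effects) on the synthetic
study written by 01_simulate.py, then the four moderator models per
response.  Writes fixed-effect tables and the moderator interaction
summary under results/raw_responses/.
"""

import sys
from pathlib import Path

import pandas as pd

from esm_affect.pipeline import AnalysisConfig, run_raw_response_analysis
from esm_affect.preprocessing import read_trials_csv

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "raw_responses"


def main() -> None:
    trials = read_trials_csv(BASE / "synthetic" / "trials.csv")
    participants = pd.read_csv(BASE / "synthetic" / "participants.csv")
    out = run_raw_response_analysis(trials, participants, AnalysisConfig(split_seed=2026))
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for outcome, section in out.items():
        section["base_fit"].to_tsv(OUT / f"{outcome}_base_fixed.tsv")
        om = section["omnibus"]
        print(f"{outcome}: category omnibus F({om['df1']:.0f}, {om['df2']:.1f}) = "
              f"{om['F']:.2f}, p = {om['p']:.2g}")
        for mod, m in section["moderators"].items():
            inter = m["interaction"]
            rows.append({
                "outcome": outcome, "moderator": mod, "F": inter["F"],
                "df2": inter["df2"], "p": inter["p"], "p_bonferroni": inter["p_bonferroni"],
                "conditional_effects_computed": m["conditional_effects"] is not None,
            })
            if m["conditional_effects"] is not None:
                m["conditional_effects"].to_csv(
                    OUT / f"{outcome}_{mod}_conditional.tsv", sep="\t"
                )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "moderator_interactions.tsv", sep="\t", index=False)
    print("\ncategory x symptom interaction tests:")
    print(summary.round(4).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
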