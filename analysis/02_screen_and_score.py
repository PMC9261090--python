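"""Data-quality screening demo: reproduce the study's exclusion census.

Builds raw response streams for 281 simulated survey takers (269 with
eligible data, of whom 8 answered carelessly with long identical-answer
runs, plus 12 who quit the rating task early), applies the two screening
rules — complete questionnaires with at least 75% task completion, and no
run of more than 50 identical answers — and writes the exclusion log.
The retained count should be 261.
"""

import sys
from pathlib import Path

from esm_affect.preprocessing import eligibility_filter, write_exclusion_log
from esm_affect.synthetic_data import simulate_raw_streams

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    streams = simulate_raw_streams(seed=SEED, n_eligible=269, n_long_string=8, n_incomplete=12)
    kept, log = eligibility_filter(streams)
    OUT.mkdir(parents=True, exist_ok=True)
    write_exclusion_log(log, OUT / "exclusion_log.tsv")
    print(f"{len(streams)} raw streams screened")
    print(log["reason"].value_counts().to_string())
    print(f"retained N = {len(kept)} (expected 261)")


if __name__ == "__main__":
    sys.exit(main())
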