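#!/usr/bin/env python
"""Traditional language-sample descriptives for the included cohort.

Applies the 20-utterance inclusion filter and reports MLU, TTR and
noun/verb token-type counts per child (results/descriptives.csv).
"""

from pathlib import Path

import pandas as pd

from recurlang.codebooks import default_codebooks
from recurlang.transcript import (filter_cohort, read_cohort,
                                  speech_descriptives)

COHORT = Path("results/cohort/transcripts")
OUT = Path("results/descriptives.csv")


def main() -> None:
    books = default_codebooks()
    transcripts = read_cohort(COHORT, books)
    kept, excluded = filter_cohort(transcripts, min_utterances=20)
    print(f"{len(kept)} children included, {len(excluded)} excluded "
          f"(< 20 utterances)")
    rows = [vars(speech_descriptives(t, books)) for t in kept]
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False, lineterminator="\n")
    print(f"wrote {OUT}")
    print(df[["total_utterances", "mlu", "ttr"]].describe()
          .loc[["mean", "min", "max"]].round(2))


if __name__ == "__main__":
    main()
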