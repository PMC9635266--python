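#!/usr/bin/env python
"""Recurrence and sequence plots for example children.

Exports the category-versus-time sequence plot and the recurrence plot
(plus its coordinate TSV) for the noun-related grammar series of the first
two included children.  Images go under scratch/figures/ (binary output);
the TSV coordinate lists sit next to them.
"""

from pathlib import Path

from recurlang.codebooks import default_codebooks
from recurlang.coding import encode
from recurlang.rqa import (export_recurrence_plot, export_sequence_plot,
                           recurrence_points)
from recurlang.transcript import filter_cohort, read_cohort

COHORT = Path("results/cohort/transcripts")
OUT = Path("scratch/figures")


def main() -> None:
    books = default_codebooks()
    kept, _ = filter_cohort(read_cohort(COHORT, books), 20)
    OUT.mkdir(parents=True, exist_ok=True)
    for t in kept[:2]:
        s = encode(t, "noun", "grammar", books)
        export_sequence_plot(s, OUT / f"{t.child_id}_noun_grammar_seq.png")
        export_recurrence_plot(recurrence_points(s),
                               OUT / f"{t.child_id}_noun_grammar_rp.png")
        print(f"{t.child_id}: plots written to {OUT}")


if __name__ == "__main__":
    main()
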