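#!/usr/bin/env python
"""Donor-identity scanning of a chimeric sequence.

Builds one chimera with a known donor tract, scans it with the
sliding-window profiler, calls donor segments, and reports how close the
called boundaries come to the planted breakpoints; then runs the 50-
replicate breakpoint-recovery experiment.

Outputs under results/04/:
    profile.tsv     per-window donor identities for the worked example
    segments.tsv    called donor segments
    recovery.tsv    planted-tract recovery rate over 50 chimeras
"""

from pathlib import Path

import numpy as np
import pandas as pd

from intron_turnover import call_segments, window_identity
from intron_turnover.experiments import mosaic_breakpoint_recovery
from intron_turnover.mosaic_scan import donor_runs, segments_table
from intron_turnover.phylo_io import Alignment
from intron_turnover.synthetic_data import evolve_sequence

OUT = Path(__file__).resolve().parent.parent / "results" / "04"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(21)
    a = "".join(rng.choice(list("ACGT"), 1200))
    b = evolve_sequence(a, 0.245, seed=22)
    start, end = 400, 650
    query = a[:start] + b[start:end] + a[end:]
    aln = Alignment(labels=["query", "A", "B"], sequences=[query, a, b])

    profile = window_identity(aln, "query", ["A", "B"], window=50, step=10)
    segments = call_segments(profile)
    profile.to_frame().to_csv(OUT / "profile.tsv", sep="\t", index=False)
    segments_table("query", segments).to_csv(
        OUT / "segments.tsv", sep="\t", index=False)
    spans = donor_runs(segments, "B")
    print(f"planted donor-B tract [{start}, {end}); "
          f"called span(s): {spans}")

    rate = mosaic_breakpoint_recovery(n_replicates=50, seed=4)
    pd.DataFrame([{"quantity": "breakpoint_recovery_rate",
                   "value": rate, "n": 50}]).to_csv(
        OUT / "recovery.tsv", sep="\t", index=False)
    print(f"breakpoint recovery within +/-40 columns: {rate:.0%} "
          f"of 50 chimeras")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
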