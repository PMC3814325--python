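#!/usr/bin/env python
"""AS-NMD prediction and splicing quantification on the fixture.

Predicts NMD substrate status for the autoregulation-like fixture (a
15-exon coding transcript whose seventh exon is a frame-breaking cassette
exon) and demonstrates the gel-quantification formulas: skipping ratios
recovered from simulated noisy band intensities, per-isoform reduction
relative to mock, and 2^-ddCt relative expression. Writes
results/nmd_report.tsv and results/skipping_recovery.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from clip_splicemap.quantify import (
    ddct_relative_expression,
    predict_nmd,
    reduction_relative_to_mock,
    skip_exon,
    skipping_ratio,
)
from clip_splicemap.simulate import fus_like_fixture, simulate_band_intensities


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    model, seq = fus_like_fixture()
    skipped, sseq = skip_exon(model, 6, seq)  # exon 7, transcript order
    calls = {"full": predict_nmd(model, seq),
             "skip_exon7": predict_nmd(skipped, sseq)}
    df = pd.DataFrame(
        {
            "isoform": list(calls),
            "frameshift": [c.frameshift for c in calls.values()],
            "ptc_position": [c.ptc_position for c in calls.values()],
            "last_junction": [c.last_junction_position for c in calls.values()],
            "ptc_to_last_junction": [c.ptc_to_last_junction for c in calls.values()],
            "nmd": [c.nmd for c in calls.values()],
        }
    )
    df.to_csv(args.outdir / "nmd_report.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    call = calls["skip_exon7"]
    print(f"\nskipping exon 7 ({len(model.exons_transcript_order()[6])} nt, "
          f"not divisible by 3) shifts the frame; first stop lands "
          f"{call.ptc_position - sum(skipped.exon_lengths_transcript_order()[:6])}"
          f" nt into the exon-8 segment, {call.ptc_to_last_junction} nt "
          f"upstream of the last junction -> NMD substrate")

    rows = []
    for truth in (0.1, 0.5, 0.9):
        pairs = simulate_band_intensities(truth, 100.0, cv=0.1, n=1000,
                                          seed=args.seed)
        mean = float(np.mean([skipping_ratio(p).skipping_ratio for p in pairs]))
        rows.append({"true_ratio": truth, "mean_recovered": mean,
                     "abs_error": abs(mean - truth)})
    rec = pd.DataFrame(rows)
    rec.to_csv(args.outdir / "skipping_recovery.tsv", sep="\t", index=False)
    print("\nskipping-ratio recovery from noisy bands (cv=0.1, n=1000):")
    print(rec.to_string(index=False))

    print("\nformula spot checks: reduction 15/100 ->",
          reduction_relative_to_mock(15, 100).fraction_of_mock,
          "; ddCt=1 ->", ddct_relative_expression(21, 15, 20, 15))


if __name__ == "__main__":
    main()
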