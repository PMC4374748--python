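#!/usr/bin/env python
"""Anchored discovery of the S-X-Y module on synthetic peak sequences.

Simulates the study's standard training data — 24 planted modules (22 at
the stringent S–X 16 / X–Y 20–22 geometry, 2 "H2-T-like" with the Y box
48 bp downstream of the X box) at 5% per-base mutation — and runs the
anchored discovery twice: with the 60-bp (stringent) and the 100-bp
(relaxed) flank windows. The stringent search cannot see the distal
H2-T-like Y boxes; the relaxed one recovers them and widens the
authorized X–Y spacing accordingly.

Writes the two fitted models (YAML), their PWMs (MEME minimal format)
and the training occurrence table under results/.
"""

from pathlib import Path

import pandas as pd

import sxyscan as sx
from sxyscan.pwm import write_meme
from sxyscan.synthetic import X_CONSENSUS, planted_peak_study

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260928


def main() -> None:
    OUT.mkdir(exist_ok=True)
    genome, truth, peak_seqs = planted_peak_study(seed=SEED)
    print(f"{len(peak_seqs)} synthetic peak sequences "
          f"({len(genome['contig_1']) // 1000} kb genome)")

    rows = []
    for window, tag in ((60, "stringent"), (100, "relaxed")):
        model = sx.discover_module(peak_seqs, window_bp=window,
                                   n_starts=10, seed=SEED + 1,
                                   reference_x=X_CONSENSUS)
        model.save(OUT / f"module_{tag}.yaml")
        write_meme([model.pwm_s, model.pwm_x, model.pwm_y],
                   OUT / f"module_{tag}.meme")
        print(f"\n{tag} ({window} bp windows): "
              f"{len(model.provenance)} complete training triplets")
        print(f"  consensus S={model.pwm_s.consensus} "
              f"X={model.pwm_x.consensus} Y={model.pwm_y.consensus}")
        print(f"  authorized spacing S-X {model.spacing_sx}, "
              f"X-Y {model.spacing_xy}")
        print(f"  thresholds S={model.threshold_s:.3f} "
              f"X={model.threshold_x:.3f} Y={model.threshold_y:.3f}")
        for entry in model.provenance:
            rows.append({
                "window_bp": window, "seq_id": entry["seq_id"],
                **{f"offset_{m.lower()}": entry["offsets"][m]
                   for m in "SXY"},
                **{f"score_{m.lower()}": round(entry["scores"][m], 4)
                   for m in "SXY"},
                "spacing_sx": entry["spacing"]["SX"],
                "spacing_xy": entry["spacing"]["XY"],
            })

    pd.DataFrame(rows).to_csv(OUT / "training_occurrences.tsv", sep="\t",
                              index=False)
    print("\nmodels and occurrence table written to results/")


if __name__ == "__main__":
    main()
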