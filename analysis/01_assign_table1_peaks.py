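#!/usr/bin/env python
"""Assign the printed NLRC5 ChIP-seq peaks to gene promoters.

The bundled site table lists the called peak intervals and the TSS of
each candidate target gene (mouse, GRCm38 browser coordinates). Applying
the strand-aware −500/+50 promoter rule reproduces the reported geometry:
of the 11 distinct called peaks, 9 overlap the promoters of 12 genes
(three peaks each serve a divergent gene pair), while the chr1 and chr15
peaks lie far from any promoter and stay unassigned.

Writes results/table1_assignment.tsv and results/table1_summary.json.
"""

import json
from pathlib import Path

import sxyscan as sx
from sxyscan import datasets

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    peaks = datasets.nlrc5_peaks()
    promoters = datasets.nlrc5_promoters()
    table, unassigned = sx.assign_peaks_to_promoters(peaks, promoters)

    table.to_csv(OUT / "table1_assignment.tsv", sep="\t", index=False)
    summary = {
        "n_called_peaks": len(peaks),
        "n_promoter_assigned_peaks": int(table.peak_id.nunique()),
        "n_promoter_genes": int(table.gene_id.nunique()),
        "unassigned_peaks": unassigned,
    }
    with open(OUT / "table1_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"{summary['n_called_peaks']} called peaks; "
          f"{summary['n_promoter_assigned_peaks']} overlap promoters of "
          f"{summary['n_promoter_genes']} genes")
    print("unassigned (distal):", ", ".join(unassigned))


if __name__ == "__main__":
    main()
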