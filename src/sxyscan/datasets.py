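"""Bundled NLRC5 ChIP-seq site table (mouse, GRCm38 coordinates).

The printed table of NLRC5-occupied sites and target genes: one row per
gene, with the peak interval that covers its promoter (several genes can
share one peak — divergent promoter pairs) and the gene's TSS with its
orientation. The H2-M3 site was found only by visual track inspection and
has no called peak interval. Peak coordinates and TSS positions are
browser-style 1-based and converted to 0-based half-open on load.
"""

from __future__ import annotations

import io

import pandas as pd

from .annotation import Peak, PromoterWindow, parse_region, \
    promoter_window_from_tss

_TABLE = """\
gene	gene_id	detection	peak	tss	tss_strand
B2m	ENSMUSG00000060802	peak_calling	chr2:122147175-122148130	122147686	+
H2-D1	ENSMUSG00000073411	peak_calling	chr17:35262463-35263394	35262730	+
H2-K1	ENSMUSG00000061232	peak_calling	chr17:34000049-34000768	34000333	-
H2-Q4	ENSMUSG00000035929	peak_calling	chr17:35379037-35380004	35379617	+
H2-Q6	ENSMUSG00000073409	peak_calling	chr17:35424724-35424884	35424850	+
H2-Q7	ENSMUSG00000060550	peak_calling	chr17:35438815-35439225	35439155	+
H2-T10	ENSMUSG00000079491	peak_calling	chr17:36121380-36122293	36121465	-
Gm19684	ENSMUSG00000092277	peak_calling	chr17:36121380-36122293	36121678	+
H2-T22	ENSMUSG00000056116	peak_calling	chr17:36042691-36043453	36042747	-
Gm6034	ENSMUSG00000073407	peak_calling	chr17:36042691-36043453	36042961	+
Tap1	ENSMUSG00000037321	peak_calling	chr17:34187312-34187863	34187553	+
Psmb9	ENSMUSG00000096727	peak_calling	chr17:34187312-34187863	34187764	-
H2-M3	ENSMUSG00000016206	visual	na	37270220	+
Aida	ENSMUSG00000042901	peak_calling	chr1:183299156-183299382	183297060	+
Ly6c2	ENSMUSG00000022584	peak_calling	chr15:75085781-75085890	75111584	-
"""

# TSS contigs: all rows share the peak's chromosome; H2-M3 sits on chr17.
_TSS_CONTIG_OVERRIDE = {"H2-M3": "chr17"}


def nlrc5_sites() -> pd.DataFrame:
    """The site table, one row per gene, coordinates as printed (1-based)."""
    return pd.read_csv(io.StringIO(_TABLE), sep="\t")


def nlrc5_peaks() -> list[Peak]:
    """The distinct called peaks (deduplicated over shared-peak genes)."""
    peaks = []
    seen = set()
    for _, row in nlrc5_sites().iterrows():
        if row["detection"] != "peak_calling" or row["peak"] == "na":
            continue
        if row["peak"] in seen:
            continue
        seen.add(row["peak"])
        contig, start, end = parse_region(row["peak"])
        peaks.append(Peak(peak_id=row["peak"], contig=contig,
                          interval=(start, end)))
    return peaks


def nlrc5_promoters(upstream_bp: int = 500,
                    downstream_bp: int = 50) -> list[PromoterWindow]:
    """Strand-aware promoter windows around every gene's printed TSS."""
    windows = []
    for _, row in nlrc5_sites().iterrows():
        if row["peak"] != "na":
            contig = row["peak"].split(":")[0]
        else:
            contig = _TSS_CONTIG_OVERRIDE[row["gene"]]
        windows.append(promoter_window_from_tss(
            gene_id=row["gene"], contig=contig,
            tss=int(row["tss"]) - 1, strand=row["tss_strand"],
            upstream_bp=upstream_bp, downstream_bp=downstream_bp,
        ))
    return windows
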