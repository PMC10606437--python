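"""Published reference values for the seven-population blackgrass
(*Alopecurus myosuroides*) circulome study that this package's analyses
are organized around.

These are inputs, not results: per-sample circle inventories (counts of
non-redundant eccDNAs, circles with predicted genes, circles with tRNAs)
and the per-phenotype eccDNA counts of the densest 500-kb windows. The
package recomputes derived quantities (percent with CDS, cohort means,
window totals) from these counts.
"""

from __future__ import annotations

# sample -> (n_ecc, mean_length, min_length, max_length, n_with_gene, n_with_trna)
INVENTORY: dict[str, tuple[int, int, int, int, int, int]] = {
    "CC2R": (4812, 7058, 31, 28_980, 1031, 53),
    "CC2S": (4233, 6994, 60, 25_087, 1010, 77),
    "CC5R": (5288, 6946, 51, 29_081, 1145, 74),
    "CC5S": (4332, 7002, 54, 28_260, 958, 45),
    "Peldon": (4443, 6868, 36, 26_368, 962, 59),
    "Lola91": (5426, 6918, 49, 27_814, 1153, 70),
    "Roth": (5663, 7040, 51, 27_090, 1291, 70),
}

# printed percent-with-CDS values (2-decimal display; Roth printed as 22.8)
PRINTED_PCT_WITH_CDS: dict[str, float] = {
    "CC2R": 21.43,
    "CC2S": 23.86,
    "CC5R": 21.65,
    "CC5S": 22.11,
    "Peldon": 21.65,
    "Lola91": 21.25,
    "Roth": 22.80,
}

GROUP_MAP: dict[str, str] = {
    "CC2R": "HR", "CC5R": "HR", "Lola91": "HR", "Peldon": "HR",
    "CC2S": "HS", "CC5S": "HS", "Roth": "HS",
}

# densest 500-kb windows: (chrom, start_bp, end_bp) -> (n_hr_ecc, n_hs_ecc)
DENSE_WINDOWS: dict[tuple[str, int, int], tuple[int, int]] = {
    ("chr1", 251_000_000, 251_500_000): (83, 48),
    ("chr5", 8_500_000, 9_000_000): (133, 104),
    ("chr5", 45_000_000, 45_500_000): (82, 55),
    ("chr7", 243_500_000, 244_000_000): (130, 80),
}
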