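"""Published reference values bundled with the package.

The per-locus forensic-parameter table for the Mongolian population
(Investigator Argus X-12 panel, pooled male+female allele frequencies,
values as printed to 4 decimals) ships as CSV package data, together with
the published multi-locus combined bounds and study sample sizes.  These are
inputs for validation, not computed results.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: study sample sizes: (males, females)
SAMPLE_SIZES = {"Mongolian": (116, 116), "EasternHan": (200, 109)}

#: published combined parameters (lower bounds, pooled frequencies, 12 loci)
COMBINED_BOUNDS = {
    "cpd_f": 0.9999999999,
    "cpd_m": 0.9999999983,
    "cmec_duo": 0.9999987070,
    "cmec_trio": 0.9999999931,
}

#: published distinct-haplotype counts per linkage group (males)
HAPLOTYPE_COUNTS = {
    "Mongolian": {"LG1": 99, "LG2": 71, "LG3": 76, "LG4": 81},
    "EasternHan": {"LG1": 159, "LG2": 94, "LG3": 101, "LG4": 114},
}

#: published haplotype diversity extremes (linkage group -> HD)
HAPLOTYPE_DIVERSITY = {
    "Mongolian": {"LG1": 0.9972, "LG2": 0.9901},
    "EasternHan": {"LG1": 0.9973, "LG3": 0.9876},
}

#: published total branch length of the 11-population UPGMA tree
UPGMA_TOTAL_BRANCH_LENGTH = 0.00821881


def mongolian_forensic_table() -> pd.DataFrame:
    """The published per-locus forensic statistics (12 loci x 11 columns),
    indexed by locus name."""
    ref = resources.files("xstrpop.data") / "mongolian_forensic_table.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("locus")
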