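"""Packaged example datasets.

``WORKED_EXAMPLE_COUNTS`` is a seven-class genotype sample (N = 120)
from a hexaploid population, used throughout the documentation.  The
chrysanthemum tables hold observed three-class frequency triples for
dosage-ambiguous SNPs from a published autohexaploid full-sib family
(a proxy for a natural population in terms of marker segregation):
one set used for aHWE testing, one for double-reduction testing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .estimation import GenotypeCounts

__all__ = [
    "WORKED_EXAMPLE_COUNTS",
    "CHRYSANTHEMUM_AHWE",
    "CHRYSANTHEMUM_DR",
    "worked_example",
    "write_fixtures",
]

WORKED_EXAMPLE_COUNTS = (29, 21, 17, 10, 10, 10, 23)

#: locus -> observed frequencies of (6A, any heterozygote, 6a)
CHRYSANTHEMUM_AHWE = {
    "SNP-4": (0.4000, 0.4875, 0.1125),
    "SNP-18": (0.5753, 0.3699, 0.0548),
    "SNP-113": (0.7826, 0.1884, 0.0290),
    "SNP-312": (0.8254, 0.1587, 0.0159),
}

CHRYSANTHEMUM_DR = {
    "SNP-5": (0.1539, 0.6593, 0.1868),
    "SNP-130": (0.6308, 0.3385, 0.0308),
    "SNP-406": (0.5303, 0.3030, 0.1667),
    "SNP-558": (0.0421, 0.3053, 0.6526),
}


def worked_example() -> GenotypeCounts:
    return GenotypeCounts(np.asarray(WORKED_EXAMPLE_COUNTS, float))


def write_fixtures(outdir) -> list:
    """Write the packaged datasets as TSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = outdir / "worked_example.tsv"
    with open(p, "w") as fh:
        fh.write("locus_id\tn_6A\tn_5A1a\tn_4A2a\tn_3A3a\tn_2A4a\tn_1A5a\tn_6a\n")
        fh.write("example-1\t" + "\t".join(str(c) for c in WORKED_EXAMPLE_COUNTS) + "\n")
    paths.append(p)

    for name, table in [
        ("chrysanthemum_ahwe.tsv", CHRYSANTHEMUM_AHWE),
        ("chrysanthemum_dr.tsv", CHRYSANTHEMUM_DR),
    ]:
        p = outdir / name
        with open(p, "w") as fh:
            fh.write("locus_id\tn_6A\tn_het\tn_6a\n")
            for locus, freqs in table.items():
                fh.write(locus + "\t" + "\t".join(f"{f:.4f}" for f in freqs) + "\n")
        paths.append(p)
    return paths
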