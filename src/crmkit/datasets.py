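"""Published reference data shipped with the package.

Small tables from the skeletal-muscle CRM validation screen: the 19
insert sequences validated as driving myotube-selective expression
(with their positive-well counts), the motif over-representation
contingency counts for the three foreground/background comparisons, and
the MyoD ChIP-peak overlap counts.  These are the printed inputs the
statistical operations are re-run on; coordinates are 1-based inclusive
as printed and converted on load.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .enrichment_stats import ContingencyTable2x2
from .io_formats import GenomicRegion, SetLabel, region_from_one_based


def validated_regions_table() -> pd.DataFrame:
    """The 19 validated (responding) inserts with set labels and well counts."""
    with resources.files("crmkit.data").joinpath("validated_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def validated_regions() -> list[GenomicRegion]:
    df = validated_regions_table()
    return [
        region_from_one_based(
            f"chr{row.chrom}",
            int(row.insert_start),
            int(row.insert_end),
            region_id=str(row.gene),
            set_label=SetLabel(row.set),
            responder=True,
        )
        for row in df.itertuples()
    ]


# Motif over-representation counts, (target hits, target non-hits,
# control hits, control non-hits) per TF, for the three comparisons:
# validated-vs-nonresponding within the background set, within the
# non-background sets, and over all sets.
ENRICHMENT_COUNTS: dict[str, dict[str, ContingencyTable2x2]] = {
    "background": {
        "RREB1": ContingencyTable2x2(3, 1, 8, 43),
        "Dl": ContingencyTable2x2(4, 0, 26, 25),
        "NHLH1": ContingencyTable2x2(3, 1, 16, 35),
    },
    "non_background": {
        "MEF2A": ContingencyTable2x2(13, 2, 116, 92),
        "NHLH1": ContingencyTable2x2(12, 3, 120, 88),
        "Fos": ContingencyTable2x2(15, 0, 181, 27),
    },
    "all": {
        "NHLH1": ContingencyTable2x2(15, 4, 136, 123),
        "RREB1": ContingencyTable2x2(8, 11, 50, 209),
        "MEF2A": ContingencyTable2x2(13, 6, 125, 134),
    },
}

# MyoD ChIP-peak overlap counts: (overlapping, total) per region set and
# cell condition, for the lifted-over responding / non-responding inserts.
MYOD_OVERLAP_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "responding": {"myoblast": (12, 43), "myotube": (25, 43)},
    "non_responding": {"myoblast": (23, 199), "myotube": (31, 199)},
}
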