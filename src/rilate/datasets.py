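"""Packaged reference dataset: the published per-sample measurements.

The study this package operationalises sealed 15 porcine carotid preparations
per instrument (marSeal 5 plus vs. BiCision) and, for every sample, reported
the lateral extent of the >50 °C critical zone, the histological necrosis
extent, and the temperature at the necrosis frontier, separately above and
below the instrument branches — 60 rows in total.  That table is shipped
verbatim as a TSV fixture so every downstream statistic can be recomputed
from raw per-sample values.

Also recorded here are the *reported* group-level numbers (means, SDs, group
indices, p-values) exactly as printed, so regression reports can show
computed-vs-reported side by side.  Reported values are data about the source
publication, never inputs to any computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import validate_measurements

INSTRUMENTS = ("marSeal", "BiCision")

#: Printed group-level values, keyed by (instrument, side).  Strings preserve
#: the printed precision (e.g. SD "3.38" vs "4.1").
REPORTED_GROUP_STATS: dict[tuple[str, str], dict[str, str]] = {
    ("marSeal", "above"): {
        "critical_mean": "2315", "critical_sd": "509.2",
        "necrosis_mean": "412.5", "necrosis_sd": "79.0",
        "frontier_mean": "64.93", "frontier_sd": "4.1",
        "rilate": "17.8",
    },
    ("marSeal", "below"): {
        "critical_mean": "1700", "critical_sd": "331.3",
        "necrosis_mean": "426.7", "necrosis_sd": "100.7",
        "frontier_mean": "63.42", "frontier_sd": "3.38",
        "rilate": "25.1",
    },
    ("BiCision", "above"): {
        "critical_mean": "2032", "critical_sd": "592.4",
        "necrosis_mean": "642.6", "necrosis_sd": "158.2",
        "frontier_mean": "60.42", "frontier_sd": "4.2",
        "rilate": "31.62",
    },
    ("BiCision", "below"): {
        "critical_mean": "1182", "critical_sd": "386.9",
        "necrosis_mean": "645.3", "necrosis_sd": "111.9",
        "frontier_mean": "55.28", "frontier_sd": "4.1",
        "rilate": "54.59",
    },
}

#: Reported two-sided p-values for the eight above-vs-below comparisons, as
#: printed ("<0.0001" is an inequality).  The index comparison for marSeal was
#: printed as exactly the significance level; it is flagged borderline
#: wherever it is reported.
REPORTED_P: dict[tuple[str, str], str] = {
    ("marSeal", "critical"): "0.0006",
    ("marSeal", "necrosis"): "0.98",
    ("marSeal", "frontier"): "0.28",
    ("marSeal", "rilate"): "0.05",
    ("BiCision", "critical"): "<0.0001",
    ("BiCision", "necrosis"): "0.9",
    ("BiCision", "frontier"): "0.002",
    ("BiCision", "rilate"): "<0.0001",
}

BORDERLINE_REPORTED: frozenset[tuple[str, str]] = frozenset({("marSeal", "rilate")})

#: Rows whose printed per-sample index disagrees with the index recomputed
#: from the same row's extents by far more than display rounding (0.81-0.98
#: index points; e.g. marSeal-above sample 13 prints 15.7 while
#: 492.8/3310 × 100 = 14.89).  Evidently transcription slips in the source
#: table; the extents are taken as authoritative and the risk class is
#: unaffected in all three.  Keyed (instrument_id, side, sample_id).
PRINTED_INDEX_DISCREPANT_ROWS: frozenset[tuple[str, str, int]] = frozenset({
    ("marSeal", "above", 13),
    ("BiCision", "above", 15),
    ("BiCision", "below", 6),
})


def table1_fixture() -> pd.DataFrame:
    """Return the packaged 60-row per-sample table.

    Columns are the canonical measurement-table columns plus
    ``rilate_printed``, the per-sample index column as printed (1 decimal;
    kept for regression comparison only — indices are always recomputed from
    the extents at full precision).
    """
    with resources.files(__package__).joinpath("data/table1.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return validate_measurements(df)
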