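"""Reference summary data from the Black Isle red kite tracking programme.

The raw telemetry of the reintroduced red kites tracked from the Black Isle
(northern Scotland, tags deployed 2009-2014) is not publicly deposited, but
the published per-bird accounting is: for each of the 24 tagged birds, the
study period, its duration in months, the total number of transmitted
fixes, and how many of those the excursion-detection algorithm assigned to
excursions. That table is reproduced here so the summary arithmetic
(percentages, totals, the overall ~5 % excursion share) can be recomputed
and checked without the raw fixes.
"""

from __future__ import annotations

import pandas as pd

# bird_id, study start, study end, duration (months), total fixes, excursion fixes
_BLACK_ISLE_ROWS = [
    ("118721", "2013-10-21", "2014-07-22", 9, 229, 46),
    ("113995", "2012-06-29", "2013-10-25", 16, 1594, 181),
    ("93834", "2009-06-23", "2010-09-13", 15, 1494, 149),
    ("54370", "2010-05-26", "2010-11-08", 6, 343, 34),
    ("93833a", "2012-06-22", "2013-11-21", 17, 1694, 162),
    ("83675", "2009-06-16", "2013-04-30", 46, 1995, 135),
    ("93831", "2009-06-21", "2009-11-14", 5, 345, 23),
    ("129013", "2013-07-16", "2013-07-25", 1, 48, 3),
    ("84169", "2012-06-19", "2014-09-28", 27, 795, 46),
    ("83673", "2009-06-15", "2010-07-03", 13, 1313, 59),
    ("113994", "2012-06-27", "2014-06-27", 24, 1227, 53),
    ("54372", "2012-06-19", "2014-10-13", 28, 2340, 99),
    ("113993", "2012-06-25", "2014-09-28", 29, 1901, 59),
    ("93835", "2009-07-03", "2014-08-27", 61, 2664, 76),
    ("83674", "2009-06-16", "2010-11-07", 17, 1468, 39),
    ("84170", "2012-06-20", "2014-10-18", 28, 1904, 39),
    ("54373", "2010-05-26", "2010-10-25", 5, 303, 5),
    ("93933b", "2009-06-23", "2010-10-09", 16, 1482, 23),
    ("83671", "2009-07-31", "2010-03-07", 9, 280, 4),
    ("93832", "2009-06-20", "2010-04-15", 10, 525, 2),
    ("54374", "2010-05-26", "2010-10-29", 5, 229, 0),
    ("54349", "2010-05-26", "2010-11-07", 6, 287, 0),
    ("54344", "2010-05-26", "2010-10-29", 5, 277, 0),
    ("83676", "2009-07-20", "2009-09-25", 2, 341, 0),
]


def black_isle_summary() -> pd.DataFrame:
    """Per-bird fix and excursion counts for the 24 Black Isle red kites.

    Columns: bird_id, study_start, study_end, duration_months, n_fixes,
    n_excursion. Percentages are deliberately *not* included; recompute
    them with :func:`kitetrails.classifier.summary_from_counts`.
    """
    df = pd.DataFrame(
        _BLACK_ISLE_ROWS,
        columns=[
            "bird_id",
            "study_start",
            "study_end",
            "duration_months",
            "n_fixes",
            "n_excursion",
        ],
    )
    df["study_start"] = pd.to_datetime(df["study_start"])
    df["study_end"] = pd.to_datetime(df["study_end"])
    return df
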