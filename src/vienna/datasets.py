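"""Published reference summaries for the VIENNA validation cohort (n = 79).

Raw per-participant data for the validation study are not public; what is
public are item-level score frequencies, chance-expected scores, and
distribution summaries.  These tables are shipped here as *inputs* so that
every derivable quantity (item means and variances, difficulty ratios,
turn-type difficulty averages, skewness/kurtosis z scores, the pilot-study
t-test) can be recomputed and checked against the published values.

Values carry the published precision (two decimals).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "item_reference_table",
    "score_reference_table",
    "pilot_reference",
    "VALIDATION_N",
]

#: size of the validation cohort
VALIDATION_N = 79

_ITEM_ROWS = [
    # item, type, ratio, mean, E, f0, f1, f2, s2, wilson_e (published)
    ("i1", "no-turn", 3.94, 1.97, 0.50, 0, 2, 77, 0.02, 0.19),
    ("i2", "no-turn", 5.42, 1.95, 0.36, 0, 4, 75, 0.05, 0.57),
    ("i3", "no-turn", 9.38, 1.97, 0.21, 1, 0, 78, 0.05, 0.66),
    ("i4", "single-turn", 6.67, 2.00, 0.30, 0, 0, 79, 0.00, 0.00),
    ("i5", "single-turn", 5.11, 1.84, 0.36, 4, 5, 70, 0.24, 0.13),
    ("i6", "single-turn", 6.24, 1.81, 0.29, 0, 15, 64, 0.16, 0.21),
    ("i7", "double-turn", 7.57, 1.59, 0.21, 8, 16, 55, 0.45, 0.53),
    ("i8", "double-turn", 3.19, 1.37, 0.43, 20, 10, 49, 0.75, 0.33),
    ("i9", "double-turn", 2.68, 0.51, 0.19, 47, 24, 8, 0.46, 0.46),
    ("i10", "full-turn", 1.91, 1.53, 0.80, 9, 19, 51, 0.48, 0.39),
    ("i11", "full-turn", 2.27, 1.41, 0.62, 1, 45, 33, 0.27, 0.44),
    ("i12", "full-turn", 2.96, 1.48, 0.50, 8, 25, 46, 0.46, 0.31),
]

_SCORE_ROWS = [
    # measure, mean, sd, median, mad, min, max, se, skew, z_skew, kurt, z_kurt
    ("vienna_total", 19.43, 2.61, 19.0, 2.97, 13, 24, 0.29, -0.29, -1.05, -0.42, -0.78),
    ("rotation_errors", 1.49, 1.12, 1.0, 1.48, 0, 4, 0.13, 0.26, 0.96, -0.80, -1.50),
    ("updating_errors", 0.59, 0.84, 0.0, 0.00, 0, 3, 0.09, 1.37, 5.06, 1.16, 2.17),
]


def item_reference_table() -> pd.DataFrame:
    """Published per-item frequencies, expected scores and summaries."""
    return pd.DataFrame(
        _ITEM_ROWS,
        columns=[
            "item_id", "item_type", "difficulty_ratio", "mean", "expected",
            "freq0", "freq1", "freq2", "variance", "wilson_e",
        ],
    ).set_index("item_id")


def score_reference_table() -> pd.DataFrame:
    """Published distribution summary of total score and error counts."""
    return pd.DataFrame(
        _SCORE_ROWS,
        columns=[
            "measure", "mean", "sd", "median", "mad", "min", "max",
            "se_mean", "skewness", "z_skew", "kurtosis_excess", "z_kurt",
        ],
    ).set_index("measure")


def pilot_reference() -> dict[str, dict[str, float]]:
    """Published pilot-study group summaries (max score 20 per version).

    The *reconstruction* group saw a faithful virtual rebuild of the original
    hallways; the *adaptation* group saw the refined symmetric layout that
    became the final assessment.
    """
    return {
        "reconstruction": {"mean": 16.86, "sd": 3.08, "n": 14, "ceiling": 3},
        "adaptation": {"mean": 16.59, "sd": 2.62, "n": 17, "ceiling": 2},
    }
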