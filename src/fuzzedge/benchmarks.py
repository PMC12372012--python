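"""Published fuzzy-evaluation benchmark values for four FLAIR MRI cases.

These are the reported percent fuzzy true positives (%FTP), fuzzy false
negatives (%FFN), fuzzy false positives (%FFP) and fuzzy index (FI) for
four ACO edge-detection operators (KH, Chi, Sin, Pow) evaluated against a
Canny reference on four brain MRI case studies (CS1, CS2, DU1, DU2).  They
serve as ready-made inputs for the statistics layer (:mod:`fuzzedge.stats`)
and its demonstrations; every summary statistic derived from them is
computed at run time.

Note the percent columns use the per-(m*n/100) normalization of graded
(not binary) membership cardinalities, so values above 100 are expected.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["benchmark_table", "CASES", "METHODS"]

CASES = ("CS1", "CS2", "DU1", "DU2")
METHODS = ("ACO_KH", "ACO_Chi", "ACO_Sin", "ACO_Pow")

_ROWS = [
    # case, method, pct_ftp, pct_ffn, pct_ffp, fi
    ("CS1", "ACO_KH", 13813.5558, 78.9893, 2545.7823, 0.8410),
    ("CS1", "ACO_Chi", 13830.1532, 78.5887, 2529.1849, 0.8420),
    ("CS1", "ACO_Sin", 13808.6418, 78.8579, 2550.6963, 0.8407),
    ("CS1", "ACO_Pow", 15490.0836, 53.9731, 869.25447, 0.9440),
    ("CS2", "ACO_KH", 14584.0047, 35.722, 1786.1172, 0.8886),
    ("CS2", "ACO_Chi", 14585.6887, 36.0614, 1784.4331, 0.8887),
    ("CS2", "ACO_Sin", 14587.8412, 35.9304, 1782.2807, 0.8888),
    ("CS2", "ACO_Pow", 15641.7746, 33.7812, 728.34729, 0.9537),
    ("DU1", "ACO_KH", 14646.0902, 39.7504, 1724.4969, 0.8925),
    ("DU1", "ACO_Chi", 14658.9086, 40.0822, 1711.6785, 0.8932),
    ("DU1", "ACO_Sin", 14656.1966, 39.7628, 1714.3904, 0.8931),
    ("DU1", "ACO_Pow", 15794.2675, 33.4020, 576.31957, 0.9631),
    ("DU2", "ACO_KH", 15211.4221, 23.1851, 1163.4043, 0.9275),
    ("DU2", "ACO_Chi", 15212.5014, 23.1170, 1162.3249, 0.9276),
    ("DU2", "ACO_Sin", 15212.4069, 23.2139, 1162.4195, 0.9276),
    ("DU2", "ACO_Pow", 15826.9928, 22.4937, 547.83357, 0.9653),
]


def benchmark_table() -> pd.DataFrame:
    """The benchmark as a tidy DataFrame (one row per case x method)."""
    return pd.DataFrame(_ROWS, columns=["case", "method", "pct_ftp", "pct_ffn", "pct_ffp", "fi"])
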