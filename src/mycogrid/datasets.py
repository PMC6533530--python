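"""Small reference tables shipped with the package.

``rice_hc_qtl_table`` is the published top-SNP summary of the putative QTLs
for hyphal colonization in the rice diversity panel screen: 23 loci from the
all-cultivars analysis plus three from subpopulation analyses (aus, tropical
japonica).  Columns: qtl, analysis, snp, chrom, pos (bp, 1-based), p, maf
(fraction), effect (percent colonization per allele).
"""

from __future__ import annotations

import pandas as pd

_QTL_ROWS = [
    ("1.1",    "All", "mlid0092747457",  1,  5069003, 4.60e-05, 0.073,  4.6),
    ("1.2",    "All", "mlid0001644797",  1,  8119524, 7.58e-05, 0.20,   4.0),
    ("1.3",    "All", "mlid0002847008",  1, 13328067, 3.37e-05, 0.21,  -4.6),
    ("1.4",    "All", "mlid0004161541",  1, 18083827, 2.15e-05, 0.39,  -5.0),
    ("2.1a",   "Aus", "mlid0014401085",  2, 22623115, 7.49e-06, 0.44, -12.7),
    ("2.2",    "All", "mlid0014856649",  2, 24494645, 6.07e-05, 0.31,   2.7),
    ("3.1",    "All", "mlid0017818601",  3,  4455505, 7.02e-05, 0.31,  -5.1),
    ("3.2",    "All", "mlid0020494652",  3, 17569164, 6.83e-06, 0.45,   5.4),
    ("3.3",    "All", "mlid0023902122",  3, 32806262, 8.53e-05, 0.11,  -7.0),
    ("4.1",    "All", "mlid0024944825",  4,  1252233, 3.92e-05, 0.14,   8.6),
    ("4.2",    "All", "mlid0029088874",  4, 16530764, 6.25e-06, 0.10,   5.3),
    ("4.3",    "All", "mlid0031764657",  4, 29353046, 2.87e-06, 0.42,   3.7),
    ("5.1",    "All", "mlid0033051374",  5,   774066, 6.90e-05, 0.19,  -4.8),
    ("6.1",    "All", "mlid0043758793",  6, 17006825, 7.81e-05, 0.11,   6.2),
    ("6.2",    "All", "mlid0046376100",  6, 28107199, 5.11e-05, 0.24,  -4.8),
    ("7.1",    "All", "mlid0048451088",  7,  7182668, 3.04e-05, 0.31,  -4.8),
    ("7.2",    "All", "mlid0052022846",  7, 20886439, 4.41e-05, 0.14,   9.1),
    ("8.1",    "All", "mlid0056191014",  8,  9715485, 4.38e-05, 0.22,   3.6),
    ("9.1",    "All", "mlid0062250420",  9,  5765734, 4.16e-05, 0.41,   5.7),
    ("10.1",   "All", "mlid0067485302", 10,  4753692, 4.47e-05, 0.073, -5.1),
    ("11.1",   "All", "mlid0076234181", 11, 17686395, 1.29e-05, 0.20,  -5.1),
    ("11.2tr", "Trj", "mlid0077311363", 11, 21793808, 1.81e-05, 0.12,  -8.1),
    ("11.2a",  "Aus", "mlid0094185850", 11, 22027960, 6.21e-05, 0.10, -10.8),
    ("12.1",   "All", "mlid0081838150", 12, 10779534, 5.12e-05, 0.19,   4.3),
    ("12.2",   "All", "mlid0082869441", 12, 14246478, 6.38e-05, 0.23,   5.2),
    ("12.3",   "All", "mlid0083460931", 12, 16261109, 9.29e-05, 0.38,   4.5),
]


def rice_hc_qtl_table() -> pd.DataFrame:
    """Published QTL top-SNP summary for hyphal colonization (26 rows)."""
    return pd.DataFrame(
        _QTL_ROWS,
        columns=["qtl", "analysis", "snp", "chrom", "pos", "p", "maf", "effect"],
    ).astype({"chrom": str})
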