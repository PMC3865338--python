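"""Small built-in fixtures: the worked-example tensor and published
intercorrelation tables for the original N=35 Heckhausen achievement-motive
sample.

The correlation tables are inputs (printed summary statistics of a historical
data set), useful for demonstrating Fisher-mean averaging of inter-item
correlations; the raw story codings behind them are not distributed here.
"""

from __future__ import annotations

from .data_model import worked_example

__all__ = [
    "worked_example",
    "HECKHAUSEN_HS_PICTURE_CORRELATIONS",
    "HECKHAUSEN_FF_PICTURE_CORRELATIONS",
    "HECKHAUSEN_HS_CATEGORY_CORRELATIONS",
    "HECKHAUSEN_FF_CATEGORY_CORRELATIONS",
]

#: pairwise Pearson correlations of the six picture-scores (A..F) on the
#: hope-of-success scale, Heckhausen sample (N = 35)
HECKHAUSEN_HS_PICTURE_CORRELATIONS: dict[tuple[str, str], float] = {
    ("A", "B"): -0.25, ("A", "C"): 0.27, ("A", "D"): 0.09,
    ("A", "E"): -0.26, ("A", "F"): 0.27,
    ("B", "C"): -0.01, ("B", "D"): -0.06, ("B", "E"): -0.04, ("B", "F"): -0.30,
    ("C", "D"): 0.42, ("C", "E"): 0.00, ("C", "F"): 0.28,
    ("D", "E"): -0.05, ("D", "F"): 0.10,
    ("E", "F"): -0.03,
}

#: same, fear-of-failure scale
HECKHAUSEN_FF_PICTURE_CORRELATIONS: dict[tuple[str, str], float] = {
    ("A", "B"): -0.10, ("A", "C"): 0.04, ("A", "D"): -0.08,
    ("A", "E"): -0.13, ("A", "F"): 0.07,
    ("B", "C"): 0.03, ("B", "D"): -0.13, ("B", "E"): 0.01, ("B", "F"): -0.27,
    ("C", "D"): 0.11, ("C", "E"): 0.05, ("C", "F"): -0.35,
    ("D", "E"): 0.28, ("D", "F"): 0.22,
    ("E", "F"): 0.35,
}

#: pairwise correlations of the six HS category-scores (incl. the ST
#: weighting category), Heckhausen sample (N = 35)
HECKHAUSEN_HS_CATEGORY_CORRELATIONS: dict[tuple[str, str], float] = {
    ("NS", "IS"): 0.08, ("NS", "ES"): -0.11, ("NS", "P"): -0.04,
    ("NS", "A+"): -0.36, ("NS", "ST"): 0.64,
    ("IS", "ES"): 0.26, ("IS", "P"): 0.00, ("IS", "A+"): 0.06,
    ("IS", "ST"): 0.36,
    ("ES", "P"): -0.13, ("ES", "A+"): 0.34, ("ES", "ST"): 0.35,
    ("P", "A+"): 0.12, ("P", "ST"): -0.13,
    ("A+", "ST"): 0.20,
}

#: pairwise correlations of the seven FF category-scores (incl. FT)
HECKHAUSEN_FF_CATEGORY_CORRELATIONS: dict[tuple[str, str], float] = {
    ("NF", "IF"): -0.05,
    ("NF", "EF"): 0.07, ("IF", "EF"): -0.06,
    ("NF", "C"): 0.22, ("IF", "C"): -0.21, ("EF", "C"): 0.28,
    ("NF", "A-"): 0.08, ("IF", "A-"): 0.01, ("EF", "A-"): 0.20,
    ("C", "A-"): 0.44,
    ("NF", "F"): 0.03, ("IF", "F"): 0.02, ("EF", "F"): 0.06,
    ("C", "F"): 0.44, ("A-", "F"): 0.40,
    ("NF", "FT"): 0.43, ("IF", "FT"): 0.02, ("EF", "FT"): 0.11,
    ("C", "FT"): 0.41, ("A-", "FT"): 0.56, ("F", "FT"): 0.53,
}
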