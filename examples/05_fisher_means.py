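"""Averaging inter-item correlations on the Fisher z scale.

Uses the published intercorrelation tables of the original N=35 Heckhausen
achievement-motive sample (built into psemetrics.datasets).  The mean
correlation of the hope-of-success picture-scores is near zero (.03) while
the category-scores average .12; for fear of failure the category mean is
.20 - the empirical footprint of the category-mode advantage.
"""

from psemetrics import fisher_mean_correlation
from psemetrics.datasets import (
    HECKHAUSEN_FF_CATEGORY_CORRELATIONS,
    HECKHAUSEN_FF_PICTURE_CORRELATIONS,
    HECKHAUSEN_HS_CATEGORY_CORRELATIONS,
    HECKHAUSEN_HS_PICTURE_CORRELATIONS,
)

for name, table in (
    ("HS pictures  ", HECKHAUSEN_HS_PICTURE_CORRELATIONS),
    ("HS categories", HECKHAUSEN_HS_CATEGORY_CORRELATIONS),
    ("FF pictures  ", HECKHAUSEN_FF_PICTURE_CORRELATIONS),
    ("FF categories", HECKHAUSEN_FF_CATEGORY_CORRELATIONS),
):
    mean_r = fisher_mean_correlation(table.values())
    print(f"{name}: mean r = {mean_r:+.2f}  ({len(table)} pairs)")
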