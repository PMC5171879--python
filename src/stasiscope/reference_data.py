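"""Published summary values used as worked-example inputs.

The field survey this pipeline emulates reported, for eight far-east
*Formica* populations, the within-population residual variances of three
characters around their allometric regressions on head width, and the
per-hour frequency of use of the fore- and hind-tibial spurs. Only these
printed summaries are public — the raw morphometric and genotype tables
were never deposited — so they serve here as inputs for the
summary-statistic operations (margins, paired t-tests, the two-sample t
from summaries).
"""

from __future__ import annotations

import pandas as pd

from .allometry import SummaryStat

#: Residual variance of each character in each population (printed units).
RESIDUAL_VARIANCES = pd.DataFrame(
    {
        "Kawayu": [20.8, 7.7, 105.7],
        "Obihiro": [30.1, 6.8, 121.4],
        "Furano": [13.3, 7.3, 29.8],
        "Moshiri": [18.5, 6.5, 32.7],
        "Ishikari": [21.3, 9.8, 143.0],
        "Ohnuma": [10.9, 6.2, 99.8],
        "Gotemba": [9.35, 5.3, 50.40],
        "Norikura": [12.0, 5.8, 59.7],
    },
    index=["FTSL", "HTL", "HTSL"],
)

#: Frequency of tibial-spur use per hour of observation (mean +/- SD, n=10
#: workers): fore-leg spur (antenna cleaning) vs hind-leg spur.
FTS_USE = SummaryStat(mean=371.9, sd=59.0, n=10)
HTS_USE = SummaryStat(mean=0.20, sd=0.40, n=10)
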