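"""Reference field data bundled with the package.

`reference_plot_counts` holds the per-plot identification results of the
commercial-field maize study the pipeline was built around: nine 5 m x 6-row
plots, three in each historical yield-stability zone (stable-high SH,
stable-medium SM, stable-low SL), flown at 4-5 m during the second leaf
collar stage.  ``n_detected`` is the algorithm's plant count for the plot
(it equals tp + fp); tp/fp/fn come from visual interpretation of the same
images; ``precision_pct``/``recall_pct`` are the published integer-percent
accuracies, kept for cross-checking.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["reference_plot_counts", "REFERENCE_PLOT_AREA_M2"]

# 5 m length x 6 rows x 0.508 m row spacing
REFERENCE_PLOT_AREA_M2 = 5.0 * 6 * 0.508

_COUNTS_CSV = """\
zone,plot,n_detected,tp,fp,fn,precision_pct,recall_pct
SH,1,131,126,5,0,96,100
SH,2,129,125,4,0,97,100
SH,3,135,131,4,4,97,97
SM,1,138,136,2,0,99,100
SM,2,141,135,6,1,96,99
SM,3,139,134,5,0,96,100
SL,1,136,133,3,0,98,100
SL,2,132,129,4,0,97,100
SL,3,139,136,3,0,98,100
"""


def reference_plot_counts() -> pd.DataFrame:
    """Per-plot detection counts from the reference field campaign."""
    return pd.read_csv(io.StringIO(_COUNTS_CSV))
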