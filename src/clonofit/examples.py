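"""Worked-example inputs.

``PANCREAS_PANEL_CORRELATION`` is the 6x6 sample correlation matrix of
mean surviving fractions measured at 1, 2, 4, 6, 8 and 10 Gy across a
nine-line human pancreatic cell panel (printed to two decimals).  All
inter-dose correlations are positive, which is why the first principal
component of such a panel acts as a weighted radioresistance index: its
eigendecomposition puts ~77% of the total variance on PC1, the only
component with eigenvalue above 1.
"""

import numpy as np

PANCREAS_PANEL_DOSES = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

PANCREAS_PANEL_CORRELATION = np.array(
    [
        [1.00, 0.83, 0.66, 0.76, 0.58, 0.58],
        [0.83, 1.00, 0.82, 0.84, 0.66, 0.33],
        [0.66, 0.82, 1.00, 0.91, 0.86, 0.54],
        [0.76, 0.84, 0.91, 1.00, 0.88, 0.68],
        [0.58, 0.66, 0.86, 0.88, 1.00, 0.81],
        [0.58, 0.33, 0.54, 0.68, 0.81, 1.00],
    ]
)
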