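"""Reference cohort of published single motor-unit scans.

Eight ultrasound-guided scanning-EMG recordings from six healthy adults
(tibialis anterior, fibular-nerve stimulation), as printed in the pilot
study that introduced the hand-stepped, ultrasound-targeted protocol. Used
as the fixed input for cohort-summary arithmetic; the raw signal data were
not deposited, so these per-recording summary rows are the only published
quantities.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["published_cohort"]

_ROWS = [
    # id, current_mA, duration mm:ss, length_mm, steps, latency_ms, dur_ms, amp_uV
    (1, 3.64, "12:07", 7.82, 5, 37.0, 5.60, 134),
    (2, 3.87, "07:54", 11.29, 8, 37.0, 5.80, 200),
    (3, 7.95, "06:38", 1.53, 4, 6.8, 5.27, 190),
    (4, 6.58, "05:04", 8.80, 6, 9.6, 10.20, 250),
    (5, 6.99, "04:05", 3.27, 3, 8.9, 9.40, 520),
    (6, 3.40, "06:34", 8.00, 3, 4.3, 7.90, 237),
    (7, 5.50, "02:59", 7.00, 5, 5.3, 7.90, 101),
    (8, 2.60, "03:33", 9.50, 4, 4.8, 2.80, 119),
]


def published_cohort() -> pd.DataFrame:
    """The eight published per-recording rows.

    Columns: ``id``, ``stimulation_current_mA``, ``experiment_duration``
    (mm:ss), ``transect_length_mm``, ``n_positions`` (traces within the
    motor unit), ``onset_latency_ms`` (earliest valid onset),
    ``mup_duration_ms`` (longest valid duration), ``max_amplitude_uV``.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "id",
            "stimulation_current_mA",
            "experiment_duration",
            "transect_length_mm",
            "n_positions",
            "onset_latency_ms",
            "mup_duration_ms",
            "max_amplitude_uV",
        ],
    )
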