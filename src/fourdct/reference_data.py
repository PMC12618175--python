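"""Published benchmark measurements from a paired clinical comparison of the
two 4DCT scan modes on one wide-detector CT platform.

Two small tables are bundled as worked-example inputs for the metric suite:

* Per-patient respiratory characteristics (n = 10; lung/liver/pancreas sites)
  measured from the external surrogate under consecutive volume and helical
  scans — the inputs to the paired TOST equivalence check.
* Representative phantom ROI statistics (mean/SD HU of target and background
  ROIs per scan mode and breathing pattern) together with the console CTDIvol
  values — the inputs to the CNR and dose-normalized-CNR worked examples.

These are measured values transcribed from the published comparison; nothing
here is computed by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "patient_respiratory_summary",
    "phantom_roi_statistics",
    "CTDI_VOL_MGY",
    "SCAN_TIME_S",
]

# Console-reported volume CT dose index per mode, mGy
CTDI_VOL_MGY = {"volume": 27.00, "helical": 33.80}

# Total acquisition time per mode for the phantom scans, seconds
SCAN_TIME_S = {"volume": 15.6, "helical": 26.6}

_PATIENTS = [
    # patient, site, roi, then (period_s, amplitude_mm, irregularity_pct)
    # for the volume scan and the helical scan
    (1, "liver", "liver", 2.59, 4.77, 8.14, 2.53, 4.78, 8.63),
    (2, "liver", "liver", 4.41, 7.92, 5.55, 4.45, 8.55, 5.29),
    (3, "lung", "target", 3.16, 2.62, 7.05, 3.19, 2.96, 7.29),
    (4, "lung", "target", 3.06, 4.07, 4.66, 2.85, 3.98, 3.10),
    (5, "lung", "target", 4.41, 3.14, 7.42, 4.41, 3.14, 7.42),
    (6, "lung", "target", 3.84, 4.38, 4.75, 3.80, 4.73, 6.51),
    (7, "pancreas", "stomach", 2.78, 3.59, 3.83, 2.78, 4.11, 4.97),
    (8, "pancreas", "gallbladder", 4.61, 2.29, 3.49, 4.58, 2.56, 4.56),
    (9, "pancreas", "stomach", 3.74, 6.38, 4.51, 3.74, 5.86, 4.50),
    (10, "pancreas", "gallbladder", 5.08, 4.85, 3.67, 5.20, 5.04, 4.49),
]

_ROI_ROWS = [
    # mode, pattern, m_roi1, sd_roi1, m_roi2, sd_roi2, cnr_ind_printed
    ("volume", "normal", -40.95, 11.61, -690.71, 61.60, 14.66),
    ("volume", "rapid", -41.30, 11.41, -689.78, 62.14, 14.52),
    ("volume", "irregular", -40.38, 11.57, -691.34, 61.77, 14.65),
    ("helical", "normal", -44.48, 14.16, -684.75, 55.02, 15.94),
    ("helical", "rapid", -44.37, 14.28, -684.05, 54.86, 15.96),
    ("helical", "irregular", -44.35, 14.38, -685.41, 55.81, 15.73),
]


def patient_respiratory_summary() -> pd.DataFrame:
    """Per-patient respiratory metrics in long form.

    Columns: patient, site, roi, mode (volume|helical), period_s,
    amplitude_mm, irregularity_pct. Paired rows (same patient, both modes).
    """
    rows = []
    for p, site, roi, pv, av, iv, ph, ah, ih in _PATIENTS:
        rows.append((p, site, roi, "volume", pv, av, iv))
        rows.append((p, site, roi, "helical", ph, ah, ih))
    return pd.DataFrame(
        rows,
        columns=[
            "patient",
            "site",
            "roi",
            "mode",
            "period_s",
            "amplitude_mm",
            "irregularity_pct",
        ],
    )


def phantom_roi_statistics() -> pd.DataFrame:
    """Representative phantom ROI statistics per mode and breathing pattern.

    Columns: mode, pattern, m_roi1, sd_roi1, m_roi2, sd_roi2 and the
    published CNR value (``cnr_ind_printed``) for cross-checking.
    """
    return pd.DataFrame(
        _ROI_ROWS,
        columns=["mode", "pattern", "m_roi1", "sd_roi1", "m_roi2", "sd_roi2", "cnr_ind_printed"],
    )
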