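"""Benchmark tables used as cross-checks of the pipeline's arithmetic.

These are fixed reference measurements for the [11C]PBR28 tracer assay:
a six-preparation dose-radioactivity table, a three-preparation plasma
concentration table (radiometric before/after correction vs LC-MS/MS), and
an eight-subject AUC table.  They are inputs to consistency tests, not
fitted or tuned by the package.
"""

# prep -> (carrier_pmol, am_gbq_per_umol, lcms_kbq, gamma_kbq, diff_pct)
DOSE_RADIOACTIVITY = {
    1: (15.2, 200.4, 3040, 4019, 32.2),
    2: (5.56, 631.1, 3510, 4817, 37.2),
    3: (12.1, 383.5, 4645, 6310, 35.8),
    4: (1.75, 904.9, 1580, 2092, 32.4),
    5: (2.901, 1124, 3261, 4249, 30.3),
    6: (2.95, 1028, 3036, 4150, 36.7),
}

# am -> list of (time_min, radiometric_uncorrected_pm, radiometric_corrected_pm, lcms_pm)
PLASMA_CONCENTRATIONS = {
    138.6: [
        (1.25, 2349.0, 1726.0, 1790.0),
        (2.50, 416.8, 306.2, 303.9),
        (20.00, 52.20, 38.36, 36.02),
        (59.98, 29.81, 21.90, 21.83),
    ],
    200.4: [
        (1.23, 1551.0, 1173.0, 1097.0),
        (2.48, 304.6, 230.4, 214.6),
        (20.18, 50.84, 38.46, 32.31),
        (60.00, 17.41, 13.17, 11.76),
    ],
    385.9: [
        (1.25, 773.8, 599.9, 594.1),
        (2.50, 140.1, 108.6, 103.7),
        (20.00, 16.48, 12.77, 11.10),
        (60.00, 7.288, 5.649, 5.158),
    ],
}

# subject -> (auc_lcms, auc_rad_uncorrected, auc_rad_corrected), kBq x min/mL
SUBJECT_AUCS = {
    1: (328.0, 470.0, 356.0),
    2: (308.0, 485.0, 351.0),
    3: (329.0, 437.0, 339.0),
    4: (332.0, 465.0, 342.0),
    5: (334.0, 500.0, 365.0),
    6: (460.0, 686.0, 505.0),
    7: (336.0, 517.0, 380.0),
    8: (518.0, 730.0, 559.0),
}

# Published summary statistics for SUBJECT_AUCS.
AUC_SUMMARY = {
    "mean_lcms": 368.0,
    "mean_rad_uncorrected": 536.0,
    "mean_rad_corrected": 399.0,
    "pct_lower_uncorrected": 31.0,
    "pct_lower_corrected": 8.0,
    "var_uncorrected": 37.0,
    "var_corrected": 8.1,
    "pearson_uncorrected": 0.97,
    "pearson_corrected": 0.99,
    "icc_uncorrected": 0.07,
    "icc_corrected": 0.91,
    "t_uncorrected": -11.9,
    "t_corrected": -6.0,
}
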