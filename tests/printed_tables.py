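"""Published monthly AUC values used as inputs to the reporting arithmetic.

These are the survey study's printed monthly cross-validated AUCs (32
training months, two model engines) and the printed projection-year AUCs
(seven months).  They serve as fixed inputs for testing the results-grid
summarisation, which must reproduce the derived row averages and
counts exactly.
"""

MONTHS = ("March", "April", "May", "June", "July", "August", "September", "October")

# (year, model_kind) -> eight monthly mean AUCs, March..October
MONTHLY_AUC = {
    (2018, "maxent"): (0.293, 0.803, 0.808, 0.685, 0.818, 0.831, 0.869, 0.902),
    (2018, "dl"): (0.822, 0.826, 0.658, 0.727, 0.779, 0.763, 0.866, 0.901),
    (2019, "maxent"): (0.606, 0.652, 0.688, 0.851, 0.836, 0.720, 0.831, 0.920),
    (2019, "dl"): (0.763, 0.811, 0.769, 0.728, 0.778, 0.851, 0.770, 0.938),
    (2020, "maxent"): (0.678, 0.437, 0.476, 0.841, 0.838, 0.753, 0.891, 0.885),
    (2020, "dl"): (0.946, 0.840, 0.785, 0.789, 0.742, 0.668, 0.871, 0.832),
    (2021, "maxent"): (0.787, 0.870, 0.855, 0.740, 0.842, 0.703, 0.511, 0.897),
    (2021, "dl"): (0.838, 0.802, 0.778, 0.749, 0.702, 0.859, 0.724, 0.924),
}

# Projection-year AUCs, March..September, plus printed yearly averages
PROJECTION_AUC = {
    "maxent": (0.651, 0.474, 0.524, 0.647, 0.575, 0.610, 0.613),
    "dl": (0.415, 0.851, 0.704, 0.549, 0.539, 0.623, 0.764),
}
PROJECTION_SIGHTINGS = (8, 2, 55, 85, 89, 25, 32)

# Derived values as printed in the study's summary tables
PRINTED_YEARLY_AVERAGES = {
    (2018, "maxent"): 0.751,
    (2019, "dl"): 0.801,
}
PRINTED_PROJECTION_AVERAGES = {"maxent": 0.585, "dl": 0.635}
PRINTED_COUNTS_ABOVE_07 = {"maxent": 23, "dl": 30}
PRINTED_PERCENT_ABOVE_07 = {"maxent": 72, "dl": 94}


def monthly_grid_records():
    return [
        (year, kind, month, auc)
        for (year, kind), row in MONTHLY_AUC.items()
        for month, auc in zip(MONTHS, row)
    ]
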