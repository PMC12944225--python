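"""Published halter-sensor field-study values used as regression targets.

Counts are TP/TN/FP/FN of minute-level one-vs-rest scoring; metrics are the
values as printed (3 decimals pooled, 2 per animal).  Duration tables are
min/24 h per animal for the baseline and unfamiliar housing conditions.
"""

# pooled over all five animals: behaviour ->
#   (duration_min, observed, detected, tp, tn, fp, fn,
#    accuracy, sensitivity, specificity, precision, kappa)
POOLED = {
    "rumination": (16024, 5790, 6525, 5146, 8854, 1380, 644,
                   0.874, 0.889, 0.865, 0.789, 0.73),
    "resting_idling": (16024, 5518, 4988, 4408, 9926, 580, 1110,
                       0.895, 0.799, 0.945, 0.884, 0.76),
    "eating": (16024, 3589, 2940, 2135, 11630, 805, 1454,
               0.859, 0.595, 0.935, 0.726, 0.57),
}
POOLED_DECIMALS = 3

# per-animal rows: behaviour -> {animal: same tuple layout as POOLED}
PER_ANIMAL = {
    "rumination": {
        "1": (3126, 1284, 1405, 969, 1406, 436, 315, 0.76, 0.75, 0.76, 0.69, 0.51),
        "2": (3785, 1542, 1663, 1447, 2027, 216, 95, 0.92, 0.94, 0.90, 0.87, 0.83),
        "3": (2620, 339, 532, 309, 2058, 223, 30, 0.90, 0.91, 0.90, 0.58, 0.65),
        "4": (3237, 1445, 1514, 1321, 1599, 193, 124, 0.90, 0.91, 0.89, 0.87, 0.80),
        "5": (3256, 1180, 1412, 1100, 1764, 312, 80, 0.88, 0.93, 0.85, 0.78, 0.75),
    },
    "resting_idling": {
        "1": (3126, 958, 1006, 748, 1910, 258, 210, 0.85, 0.78, 0.88, 0.74, 0.65),
        "2": (3785, 1148, 1016, 938, 2559, 78, 210, 0.92, 0.82, 0.97, 0.92, 0.81),
        "3": (2620, 1530, 1451, 1378, 1017, 73, 152, 0.91, 0.90, 0.93, 0.95, 0.83),
        "4": (3237, 718, 486, 357, 2390, 129, 361, 0.85, 0.50, 0.95, 0.73, 0.50),
        "5": (3256, 1164, 1029, 987, 2050, 42, 177, 0.93, 0.85, 0.98, 0.96, 0.85),
    },
    "eating": {
        "1": (3126, 644, 349, 249, 2382, 100, 395, 0.84, 0.39, 0.96, 0.71, 0.42),
        "2": (3785, 853, 855, 647, 2724, 208, 206, 0.89, 0.76, 0.93, 0.76, 0.69),
        "3": (2620, 639, 380, 328, 1929, 52, 311, 0.86, 0.51, 0.97, 0.86, 0.56),
        "4": (3237, 704, 927, 593, 2199, 334, 111, 0.86, 0.84, 0.87, 0.64, 0.64),
        "5": (3256, 749, 429, 318, 2396, 111, 431, 0.83, 0.42, 0.96, 0.74, 0.45),
    },
}
PER_ANIMAL_DECIMALS = 2

# the one printed inconsistency: pooled rumination Detected (6525) is one off
# from TP+FP (6526); every other row satisfies observed=TP+FN, detected=TP+FP
KNOWN_DETECTED_OFFSET = ("rumination", 6525, 6526)

# 24 h duration tables (min/24 h) per animal, posture-free rows:
# behaviour -> (baseline 4-tuple, unfamiliar 4-tuple,
#               printed mean/sd pairs, printed p, expected test)
DAILY_ANY = {
    "rumination": ((451, 476, 474, 541), (318, 274, 188, 276),
                   (485.5, 38.7, 264.0, 54.6), 0.00764, "paired_t"),
    "resting_idling": ((632, 594, 692, 630), (913, 934, 1064, 859),
                       (637.0, 40.6, 942.5, 86.9), 0.00237, "paired_t"),
    "eating": ((331, 299, 240, 200), (162, 162, 160, 198),
               (267.5, 58.7, 170.5, 18.4), 0.125, "paired_wilcoxon"),
    "other": ((26, 71, 34, 69), (47, 70, 28, 107),
              (50.0, 23.3, 63.0, 34.0), 0.292, "paired_t"),
}

# posture-split rows: (behaviour, posture) -> same layout
DAILY_POSTURE = {
    ("rumination", "lying"): ((373, 461, 444, 455), (208, 268, 163, 257),
                              (433.3, 40.8, 224.0, 48.3), 0.00357, "paired_t"),
    ("rumination", "standing"): ((78, 15, 30, 86), (110, 6, 25, 19),
                                 (52.2, 35.0, 40.0, 47.3), 0.5914, "paired_t"),
    ("resting_idling", "lying"): ((518, 544, 403, 490), (548, 689, 557, 374),
                                  (488.8, 61.3, 542.0, 129.2), 0.461, "paired_t"),
    ("resting_idling", "standing"): ((114, 50, 289, 140), (365, 245, 507, 485),
                                     (148.2, 101.2, 400.5, 121.0), 0.00464,
                                     "paired_t"),
}

# abstract-level percent changes of the mean daily budgets
PERCENT_CHANGES = {
    "rumination": -45.6,
    "resting_idling": 47.9,
    "eating": -36.2,
}

ANIMALS = ("1", "2", "3", "4")


def duration_frame():
    """The posture-free duration table as the package's CSV-dialect frame."""
    import pandas as pd

    rows = []
    for behaviour, (base, unf, *_rest) in DAILY_ANY.items():
        for animal, b, u in zip(ANIMALS, base, unf):
            rows.append((animal, "baseline", behaviour, "any", b))
            rows.append((animal, "unfamiliar", behaviour, "any", u))
    return pd.DataFrame(
        rows, columns=["animal", "condition", "behaviour", "posture", "minutes"]
    )


def posture_duration_frame():
    """Posture-split duration rows (lying/standing only)."""
    import pandas as pd

    rows = []
    for (behaviour, posture), (base, unf, *_rest) in DAILY_POSTURE.items():
        for animal, b, u in zip(ANIMALS, base, unf):
            rows.append((animal, "baseline", behaviour, posture, b))
            rows.append((animal, "unfamiliar", behaviour, posture, u))
    return pd.DataFrame(
        rows, columns=["animal", "condition", "behaviour", "posture", "minutes"]
    )
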