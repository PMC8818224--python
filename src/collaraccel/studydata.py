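"""Published reference tables from the captive-cheetah dual-logger trials.

Inputs for the arithmetic checks and the device-comparison re-analysis:
the per-behaviour event counts at fine resolution for each logger, and the
per-behaviour validation categorisation accuracies (%) at each model
resolution. These are observed quantities, carried as data; everything
derived from them (collapsed aggregates, percent differences, mean
differences, 2x2 test statistics) is recomputed by this package.
"""

from __future__ import annotations

DEVICES = ("CEFAS", "GCDC")

#: Fine-resolution logging-event counts per behaviour, one column per logger.
FINE_EVENT_COUNTS: dict[str, dict[str, int]] = {
    "CEFAS": {
        "crouch": 638, "lie": 32056, "sit": 2389, "stand": 13842,
        "head movement": 1429, "crouching stalk": 96, "lying stalk": 11692,
        "sitting stalk": 119, "standing stalk": 1330, "walking stalk": 3024,
        "trotting stalk": 1267, "walk": 6651, "trot": 1295, "canter": 3039,
        "gallop": 4154, "pounce": 87, "other": 20466,
    },
    "GCDC": {
        "crouch": 1087, "lie": 54544, "sit": 4061, "stand": 23536,
        "head movement": 2405, "crouching stalk": 163, "lying stalk": 19933,
        "sitting stalk": 204, "standing stalk": 2201, "walking stalk": 5132,
        "trotting stalk": 2129, "walk": 11161, "trot": 2165, "canter": 4985,
        "gallop": 6976, "pounce": 141, "other": 32549,
    },
}

#: Validation categorisation accuracy (%) per behaviour, logger, resolution.
#: Only behaviours present in a resolution's vocabulary appear ("other" is
#: disregarded in the published per-behaviour reporting).
CATEGORISATION_ACCURACY: dict[str, dict[str, dict[str, float]]] = {
    "fine": {
        "CEFAS": {
            "crouch": 35.6, "lie": 92.6, "sit": 79.7, "stand": 90.4,
            "head movement": 55.1, "crouching stalk": 78.9,
            "lying stalk": 93.5, "sitting stalk": 96.3,
            "standing stalk": 78.5, "walking stalk": 58.2,
            "trotting stalk": 47.4, "walk": 75.8, "trot": 37.4,
            "canter": 51.0, "gallop": 78.2, "pounce": 4.8,
        },
        "GCDC": {
            "crouch": 49.3, "lie": 95.3, "sit": 86.6, "stand": 87.8,
            "head movement": 65.9, "crouching stalk": 65.8,
            "lying stalk": 92.8, "sitting stalk": 100.0,
            "standing stalk": 79.9, "walking stalk": 65.1,
            "trotting stalk": 56.3, "walk": 77.9, "trot": 53.5,
            "canter": 54.8, "gallop": 69.4, "pounce": 56.0,
        },
    },
    "medium": {
        "CEFAS": {
            "head movement": 53.4, "crouching stalk": 63.2,
            "lying stalk": 93.2, "sitting stalk": 92.6,
            "standing stalk": 77.7, "walk": 73.1, "trot": 34.5,
            "canter": 49.1, "gallop": 77.5, "sedentary": 95.0,
            "moving stalk": 59.2,
        },
        "GCDC": {
            "head movement": 57.1, "crouching stalk": 65.8,
            "lying stalk": 92.3, "sitting stalk": 100.0,
            "standing stalk": 78.6, "walk": 74.6, "trot": 50.2,
            "canter": 53.4, "gallop": 67.9, "sedentary": 95.4,
            "moving stalk": 69.2,
        },
    },
    "coarse": {
        "CEFAS": {"head movement": 50.3, "active": 86.9, "inactive": 95.5},
        "GCDC": {"head movement": 61.3, "active": 88.3, "inactive": 95.0},
    },
}
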