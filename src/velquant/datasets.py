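"""Reference values from the published VELscope lesion-classification study.

The clinical images behind the original study are not deposited, but its
confusion tables, performance tables and cohort bookkeeping are printed
and can be recomputed exactly.  This module carries those printed numbers
so the metric pipeline can be validated against them:

* ``CONFUSION_TABLES[subsite][classifier][normalization][partition]`` —
  3x3 counts in class order N, M, PM, rows = actual, columns = predicted.
* ``PERFORMANCE_TABLES`` — the corresponding printed per-class
  (precision, recall, f1) triples, same nesting, two decimal places.
* ``COHORT_COUNTS`` — images per subsite and class (340 total).

A few printed performance entries disagree with their own confusion
counts by more than rounding (e.g. a recall of 38/43 = 0.88 printed as
0.86); ``KNOWN_INCONSISTENT`` enumerates them so exact recomputation
checks can treat them as typos rather than failures.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .evaluation import ConfusionTable

CLASS_ORDER: Tuple[str, str, str] = ("N", "M", "PM")

#: Images per subsite and class; five images per participant.
COHORT_COUNTS: Dict[str, Dict[str, int]] = {
    "tongue": {"N": 55, "PM": 55, "M": 40},
    "buccal": {"N": 50, "PM": 100, "M": 40},
}

TRAIN_FRACTION = 0.75

_RAW_CONFUSIONS = {
    "tongue": {
        "lda": {
            "unnormalized": {
                "training": [[24, 10, 5], [17, 12, 1], [4, 1, 38]],
                "testing": [[8, 5, 3], [7, 3, 0], [1, 1, 10]],
            },
            "normalized": {
                "training": [[36, 0, 4], [2, 31, 1], [6, 2, 30]],
                "testing": [[12, 0, 3], [0, 6, 0], [3, 1, 13]],
            },
        },
        "qda": {
            "unnormalized": {
                "training": [[28, 6, 5], [12, 17, 1], [7, 0, 36]],
                "testing": [[13, 0, 3], [7, 3, 0], [2, 0, 10]],
            },
            "normalized": {
                "training": [[36, 1, 3], [2, 31, 1], [4, 2, 32]],
                "testing": [[12, 1, 2], [0, 6, 0], [1, 1, 15]],
            },
        },
    },
    "buccal": {
        "lda": {
            "unnormalized": {
                "training": [[10, 2, 28], [10, 11, 9], [8, 7, 57]],
                "testing": [[3, 0, 7], [4, 1, 5], [5, 1, 22]],
            },
            "normalized": {
                "training": [[21, 0, 17], [1, 22, 6], [3, 4, 68]],
                "testing": [[4, 0, 8], [1, 6, 4], [3, 3, 19]],
            },
        },
        "qda": {
            "unnormalized": {
                "training": [[29, 1, 10], [13, 4, 13], [15, 5, 52]],
                "testing": [[7, 0, 3], [2, 4, 4], [11, 1, 16]],
            },
            "normalized": {
                "training": [[35, 0, 3], [0, 20, 9], [8, 2, 65]],
                "testing": [[9, 0, 3], [0, 8, 3], [5, 2, 18]],
            },
        },
    },
}

#: Published confusion tables as ConfusionTable objects.
CONFUSION_TABLES: Dict[str, Dict[str, Dict[str, Dict[str, ConfusionTable]]]] = {
    subsite: {
        clf: {
            norm: {
                part: ConfusionTable(CLASS_ORDER, np.array(counts))
                for part, counts in parts.items()
            }
            for norm, parts in norms.items()
        }
        for clf, norms in clfs.items()
    }
    for subsite, clfs in _RAW_CONFUSIONS.items()
}

#: Printed per-class (precision, recall, f1), same nesting as above.
PERFORMANCE_TABLES: Dict[str, Dict] = {
    "tongue": {
        "lda": {
            "unnormalized": {
                "training": {"N": (0.53, 0.62, 0.57), "M": (0.52, 0.40, 0.45), "PM": (0.86, 0.86, 0.87)},
                "testing": {"N": (0.50, 0.50, 0.50), "M": (0.33, 0.30, 0.32), "PM": (0.77, 0.83, 0.80)},
            },
            "normalized": {
                "training": {"N": (0.82, 0.90, 0.86), "M": (0.94, 0.91, 0.93), "PM": (0.86, 0.79, 0.82)},
                "testing": {"N": (0.80, 0.80, 0.80), "M": (0.86, 1.00, 0.92), "PM": (0.81, 0.76, 0.79)},
            },
        },
        "qda": {
            "unnormalized": {
                "training": {"N": (0.60, 0.72, 0.65), "M": (0.74, 0.57, 0.64), "PM": (0.86, 0.84, 0.85)},
                "testing": {"N": (0.59, 0.81, 0.68), "M": (1.00, 0.30, 0.46), "PM": (0.77, 0.83, 0.80)},
            },
            "normalized": {
                "training": {"N": (0.86, 0.90, 0.88), "M": (0.91, 0.91, 0.91), "PM": (0.89, 0.84, 0.86)},
                "testing": {"N": (0.92, 0.80, 0.86), "M": (0.75, 1.00, 0.86), "PM": (0.88, 0.88, 0.88)},
            },
        },
    },
    "buccal": {
        "lda": {
            "unnormalized": {
                "training": {"N": (0.36, 0.25, 0.29), "M": (0.55, 0.37, 0.44), "PM": (0.61, 0.79, 0.69)},
                "testing": {"N": (0.25, 0.30, 0.27), "M": (0.50, 0.10, 0.17), "PM": (0.65, 0.79, 0.71)},
            },
            "normalized": {
                "training": {"N": (0.84, 0.55, 0.67), "M": (0.85, 0.76, 0.80), "PM": (0.75, 0.91, 0.82)},
                "testing": {"N": (0.50, 0.33, 0.40), "M": (0.67, 0.55, 0.60), "PM": (0.61, 0.76, 0.68)},
            },
        },
        "qda": {
            "unnormalized": {
                "training": {"N": (0.51, 0.72, 0.60), "M": (0.40, 0.13, 0.20), "PM": (0.69, 0.72, 0.71)},
                "testing": {"N": (0.35, 0.70, 0.47), "M": (0.80, 0.40, 0.53), "PM": (0.70, 0.57, 0.63)},
            },
            "normalized": {
                "training": {"N": (0.81, 0.92, 0.86), "M": (0.91, 0.69, 0.78), "PM": (0.84, 0.87, 0.86)},
                "testing": {"N": (0.64, 0.75, 0.69), "M": (0.80, 0.73, 0.76), "PM": (0.75, 0.72, 0.73)},
            },
        },
    },
}

#: Published accuracy percentages that are consistent with the confusion
#: counts (trace / total * 100).
PUBLISHED_ACCURACY_PCT = {
    ("tongue", "qda", "normalized", "training"): 88.0,   # 99 / 112
    ("buccal", "qda", "normalized", "training"): 84.0,   # 120 / 142
}

#: (subsite, classifier, normalization, partition, class, metric) entries of
#: PERFORMANCE_TABLES whose printed value differs from the value recomputed
#: from the study's own confusion counts by more than printing precision
#: (> 0.005).  Populated from an exhaustive recomputation; treated as typos.
KNOWN_INCONSISTENT = frozenset(
    {
        # printed 0.86; the counts give 38/43 = 0.88, and the printed f1 of
        # 0.87 is the harmonic mean of (0.86, 0.88), not of (0.86, 0.86)
        ("tongue", "lda", "unnormalized", "training", "PM", "recall"),
    }
)
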