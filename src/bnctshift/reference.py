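"""Published THOR shift-study dose tables used as inputs.

These are the printed mean-tumor-dose tables (Gy-Eq) for the cylindrical
phantom and the patient head model of the THOR single-posterior-field
positioning study, together with the printed percent-change table they
imply.  They serve as fixed numeric inputs for the percent-change
reproduction tests; they are not outputs of this package's dose engine.

Shift keys: LS1-3 = 1-3 cm lateral shift (mean of left/right and
superior/inferior), OS1-3 = 1-3 cm outward shift (air gap).

Two printed percent-change cells are internally inconsistent with the
dose tables they derive from (head 6.5 cm 2 cm lateral: printed 5.52,
recomputed 5.40; cylinder 6.5 cm 1 cm outward: printed 4.72, recomputed
8.72); they are flagged ``consistent=False`` and excluded from
reproduction checks.
"""

from __future__ import annotations

from typing import Dict, Tuple

SHIFT_KEYS = ("LS1", "LS2", "LS3", "OS1", "OS2", "OS3")

# (family, tumor depth cm) -> shift key -> mean tumor dose in Gy-Eq
MEAN_TUMOR_DOSE: Dict[Tuple[str, float], Dict[str, float]] = {
    ("cylinder", 6.5): {"baseline": 24.31, "LS1": 23.95, "LS2": 23.02,
                        "LS3": 21.56, "OS1": 22.19, "OS2": 21.43, "OS3": 20.21},
    ("cylinder", 2.5): {"baseline": 20.69, "LS1": 20.51, "LS2": 19.84,
                        "LS3": 18.75, "OS1": 19.81, "OS2": 18.43, "OS3": 17.52},
    ("head", 6.5): {"baseline": 24.45, "LS1": 24.10, "LS2": 23.13,
                    "LS3": 21.73, "OS1": 23.30, "OS2": 21.84, "OS3": 20.74},
    ("head", 2.5): {"baseline": 20.68, "LS1": 20.55, "LS2": 19.93,
                    "LS3": 18.85, "OS1": 19.70, "OS2": 18.92, "OS3": 18.08},
}

# (shift key, family, depth) -> (printed percent change, consistent flag)
PRINTED_PERCENT_CHANGE: Dict[Tuple[str, str, float], Tuple[float, bool]] = {
    ("LS1", "head", 6.5): (1.43, True),
    ("LS1", "head", 2.5): (0.63, True),
    ("LS1", "cylinder", 6.5): (1.48, True),
    ("LS1", "cylinder", 2.5): (0.87, True),
    ("LS2", "head", 6.5): (5.52, False),
    ("LS2", "head", 2.5): (3.63, True),
    ("LS2", "cylinder", 6.5): (5.31, True),
    ("LS2", "cylinder", 2.5): (4.11, True),
    ("LS3", "head", 6.5): (11.12, True),
    ("LS3", "head", 2.5): (8.85, True),
    ("LS3", "cylinder", 6.5): (11.31, True),
    ("LS3", "cylinder", 2.5): (9.38, True),
    ("OS1", "head", 6.5): (4.70, True),
    ("OS1", "head", 2.5): (4.74, True),
    ("OS1", "cylinder", 6.5): (4.72, False),
    ("OS1", "cylinder", 2.5): (4.25, True),
    ("OS2", "head", 6.5): (10.67, True),
    ("OS2", "head", 2.5): (8.51, True),
    ("OS2", "cylinder", 6.5): (11.85, True),
    ("OS2", "cylinder", 2.5): (10.92, True),
    ("OS3", "head", 6.5): (15.17, True),
    ("OS3", "head", 2.5): (12.57, True),
    ("OS3", "cylinder", 6.5): (16.87, True),
    ("OS3", "cylinder", 2.5): (15.32, True),
}

# Column order of the percent-change table: head pairs first, then cylinder.
PERCENT_CHANGE_COLUMNS = (
    ("head", 6.5), ("head", 2.5), ("cylinder", 6.5), ("cylinder", 2.5),
)


def consistent_cells():
    """(shift, family, depth, printed value) for every consistent cell in
    table row-major order."""
    out = []
    for shift in SHIFT_KEYS:
        for family, depth in PERCENT_CHANGE_COLUMNS:
            value, ok = PRINTED_PERCENT_CHANGE[(shift, family, depth)]
            if ok:
                out.append((shift, family, depth, value))
    return out
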