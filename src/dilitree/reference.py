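"""Published reference counts used as regression fixtures.

These are the printed evaluation tables of the original screening study:
the final tree model's confusion matrix, the class-by-threshold contingency
counts of the AMW >= 7.4 screen, and the occupancy of the second decision
node (AMW < 7.4 and MLOGP < -0.454).  They are inputs, not outputs — the
package recomputes every derived statistic from them.
"""

from __future__ import annotations

from .metrics import ConfusionMatrix

__all__ = [
    "FINAL_MODEL_CONFUSION",
    "AMW_SCREEN_COUNTS",
    "SECOND_NODE_COUNTS",
    "expand_counts",
]

#: Final tree model: actual DILI predicted DILI 384, actual DILI predicted
#: no-DILI 48, actual no-DILI predicted DILI 90, actual no-DILI predicted
#: no-DILI 130 (652 drugs, 432 DILI : 220 no-DILI).
FINAL_MODEL_CONFUSION = ConfusionMatrix(tp=384, tn=130, fp=90, fn=48)

#: AMW-screen contingency counts per DILI subclass: (n with AMW >= 7.4,
#: n with AMW < 7.4).
AMW_SCREEN_COUNTS: dict[str, tuple[int, int]] = {
    "Most": (120, 55),
    "Less": (156, 101),
    "No": (64, 156),
}

#: Second decision node (AMW < 7.4 and MLOGP < -0.454): total occupancy and
#: how many of those drugs are no-DILI.
SECOND_NODE_COUNTS = {"total": 29, "no_dili": 28}


def expand_counts(
    counts: dict[str, tuple[int, int]],
    ge_value: float = 8.0,
    lt_value: float = 7.0,
) -> tuple[list[float], list[str]]:
    """Expand per-class (>= , <) counts into per-drug AMW values and class
    labels suitable for the contingency-report operation.  Placeholder AMW
    values sit on the correct side of the 7.4 boundary."""
    amw_values: list[float] = []
    classes: list[str] = []
    for cls, (n_ge, n_lt) in counts.items():
        amw_values.extend([ge_value] * n_ge + [lt_value] * n_lt)
        classes.extend([cls] * (n_ge + n_lt))
    return amw_values, classes
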