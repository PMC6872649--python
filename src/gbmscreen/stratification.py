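"""Percentile-based sensitivity stratification of a cell-line panel.

Cell lines are ranked on a sensitivity metric — viability at a common dose,
or dose-response AUC — and split at the realized 25th and 75th percentiles:
values strictly below P25 are *sensitive*, strictly above P75 *resistant*,
everything in between (boundaries included) *intermediate*.  Percentiles use
linear interpolation between closest ranks, so the stratification depends on
the metric only through its ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

SENSITIVE = "sensitive"
INTERMEDIATE = "intermediate"
RESISTANT = "resistant"
CLASSES = (SENSITIVE, INTERMEDIATE, RESISTANT)


@dataclass(frozen=True)
class SensitivityCall:
    cell_line: str
    metric: str
    value: float
    class_label: str
    cutoff_low: float
    cutoff_high: float


def stratify(values: Mapping[str, float], metric: str = "viability_at_common_ec50") -> list[SensitivityCall]:
    """Classify each cell line by the panel's 25th/75th percentile cutoffs.

    value < P25 -> sensitive; P25 <= value <= P75 -> intermediate;
    value > P75 -> resistant.  Ties share a class by construction.
    """
    if len(values) < 4:
        raise ValidationError(f"panel too small for percentile stratification: {len(values)} < 4")
    vals = np.array([values[k] for k in values], dtype=float)
    if np.any(~np.isfinite(vals)):
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        raise ValidationError(f"non-finite metric values for: {bad}")
    p25, p75 = np.percentile(vals, [25.0, 75.0], method="linear")
    calls = []
    for line, v in values.items():
        if v < p25:
            label = SENSITIVE
        elif v > p75:
            label = RESISTANT
        else:
            label = INTERMEDIATE
        calls.append(SensitivityCall(line, metric, float(v), label, float(p25), float(p75)))
    return calls


def compare_stratifications(
    calls_a: list[SensitivityCall], calls_b: list[SensitivityCall]
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Cross-tabulate two stratifications of the same panel.

    Returns the 3x3 contingency table (rows = classes under A, columns =
    classes under B) and the list of class-shifted lines as
    (cell_line, class_under_a, class_under_b) tuples.
    """
    a = {c.cell_line: c.class_label for c in calls_a}
    b = {c.cell_line: c.class_label for c in calls_b}
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise KeyError(f"panels differ; symmetric difference: {diff}")
    tab = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    shifts = []
    for line in sorted(a):
        tab.loc[a[line], b[line]] += 1
        if a[line] != b[line]:
            shifts.append((line, a[line], b[line]))
    return tab, shifts
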