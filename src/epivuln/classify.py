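"""Four-class vulnerability delimitation by the mean ± SD rule.

Districts are assigned to classes I–IV from a synthetic index using the
arithmetic mean (Rav) and sample standard deviation (s) of the index:

* I   (low vulnerability):        Ri > Rav + s
* II  (medium):                   Rav < Ri ≤ Rav + s
* III (quite high):               Rav − s < Ri ≤ Rav
* IV  (high):                     Ri ≤ Rav − s

A *lower* index means a *more* vulnerable district, so class number grows
as the index falls.  Boundary values are assigned to the more vulnerable
(higher-numbered) class — a conservative choice for a screening
instrument.  Classification may alternatively be run on the ranks of the
index values (``method="ranks"``); the class *rule* is identical, applied
to ranks instead of values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_ORDER = ["I", "II", "III", "IV"]
CLASS_LABELS = {"I": "low", "II": "medium", "III": "quite high", "IV": "high"}


class ClassificationError(ValueError):
    """Raised on invalid classification inputs."""


@dataclass
class VulnerabilityClassification:
    """Class I–IV per district with the cutoffs that produced them."""

    classes: pd.Series  # ordered categorical with categories I..IV
    values: pd.Series  # the values the rule was applied to (index or ranks)
    rav: float
    s: float
    method: str = "values"

    @property
    def cutoffs(self) -> dict[str, float]:
        return {
            "rav_plus_s": self.rav + self.s,
            "rav": self.rav,
            "rav_minus_s": self.rav - self.s,
        }

    @property
    def counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(CLASS_ORDER, fill_value=0)

    def members(self, numeral: str) -> list:
        return self.classes.index[self.classes == numeral].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "class": self.classes,
                "label": self.classes.map(CLASS_LABELS),
            }
        )


def classify(index: pd.Series, method: str = "values") -> VulnerabilityClassification:
    """Delimit four vulnerability classes from a per-district index."""
    if method not in {"values", "ranks"}:
        raise ClassificationError(f"unknown classification method {method!r}")
    values = pd.Series(index, dtype=float)
    if len(values) < 2:
        raise ClassificationError("classification requires at least 2 districts")
    if not np.isfinite(values).all():
        raise ClassificationError("index values must be finite")
    if method == "ranks":
        values = values.rank(method="average")
    rav = float(values.mean())
    s = float(values.std(ddof=1))
    labels = np.full(len(values), "III", dtype=object)
    if s == 0.0:
        # degenerate spread: every district sits on all three cutoffs at
        # once; assign the middle class rather than the boundary rule
        warnings.warn(
            "index has zero variance; every district falls in class III",
            stacklevel=2,
        )
    else:
        labels[values > rav] = "II"
        labels[values > rav + s] = "I"
        labels[values <= rav - s] = "IV"
    classes = pd.Series(
        pd.Categorical(labels, categories=CLASS_ORDER, ordered=True),
        index=values.index,
    )
    return VulnerabilityClassification(
        classes=classes, values=values, rav=rav, s=s, method=method
    )


def crosstab_classes(
    a: VulnerabilityClassification, b: VulnerabilityClassification
) -> pd.DataFrame:
    """4×4 contingency table of joint class membership for two
    classifications of the same district set."""
    if set(a.classes.index) != set(b.classes.index):
        raise ClassificationError("classifications cover different district sets")
    tab = pd.crosstab(a.classes, b.classes.reindex(a.classes.index), dropna=False)
    return tab.reindex(index=CLASS_ORDER, columns=CLASS_ORDER, fill_value=0)
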