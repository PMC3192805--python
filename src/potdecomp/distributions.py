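"""Class-resolved Gaussian summaries of contact free-energy distributions.

Native-fold potentials show three well-separated Gaussian components, one per
hydropathy class of the contacting pair (H-H, H-P, P-P); beta-strand pairing
potentials show a single narrow Gaussian for polar and non-polar contacts
alike.  "Gaussian fit" here means sample moments (the Gaussian MLE), which is
deterministic and bin-free; component weights follow the element-count
convention (class size over the number of unique elements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import pair_class
from .matrices import ContactMatrix, HydropathyClassification

CLASS_ORDER = ("HH", "HP", "PP")


@dataclass
class GaussianComponents:
    """Per-class (H-H, H-P, P-P) weight fraction, mean and population sd."""

    weights: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    weighting: str = "element_count"

    def component(self, cls: str) -> tuple[float, float, float]:
        return self.weights[cls], self.means[cls], self.sds[cls]


def class_partition(
    matrix: ContactMatrix, classification: HydropathyClassification
) -> dict[str, np.ndarray]:
    """Split the unique elements into the H-H, H-P and P-P classes.

    Every unique element lands in exactly one class; under the default
    ten/ten split the sizes are 55, 100 and 55.
    """
    pairs, values = matrix.unique_elements()
    out: dict[str, list[float]] = {c: [] for c in CLASS_ORDER}
    for (a, b), v in zip(pairs, values):
        out[pair_class(classification, a, b)].append(v)
    return {c: np.array(vs) for c, vs in out.items()}


def class_gaussians(
    matrix: ContactMatrix,
    classification: HydropathyClassification,
    weighting: str = "element_count",
) -> GaussianComponents:
    """Gaussian (moment) decomposition of the contact free energies by class."""
    if weighting != "element_count":
        raise ValueError("only the element_count weighting convention is implemented")
    parts = class_partition(matrix, classification)
    total = sum(len(v) for v in parts.values())
    for c, v in parts.items():
        if len(v) == 0:
            raise ValueError(f"class {c} is empty under {classification.name!r}")
    return GaussianComponents(
        weights={c: len(v) / total for c, v in parts.items()},
        means={c: float(np.mean(v)) for c, v in parts.items()},
        sds={c: float(np.std(v)) for c, v in parts.items()},
    )


def single_gaussian(matrix: ContactMatrix) -> tuple[float, float]:
    """Mean and population sd of all unique elements (single-Gaussian summary)."""
    _, values = matrix.unique_elements()
    return float(np.mean(values)), float(np.std(values))


def histogram_export(matrix: ContactMatrix, bin_width: float) -> pd.DataFrame:
    """Histogram of the unique elements with fixed-width bins.

    Bins are anchored at the smallest element (so shifting every element by a
    constant shifts the bin positions but never the counts); the counts sum
    to the number of unique elements.  Returned as a tidy table with columns
    ``bin_left``, ``bin_right``, ``bin_center`` and ``count``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    _, values = matrix.unique_elements()
    n_bins = max(1, int(np.floor((values.max() - values.min()) / bin_width)) + 1)
    edges = values.min() + np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "bin_center": (edges[:-1] + edges[1:]) / 2.0,
            "count": counts,
        }
    )
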