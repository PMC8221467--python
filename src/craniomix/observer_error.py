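"""Intra-observer digitization error assessment.

One cranium digitised several times yields repeat configurations; the
protocol compares the greatest pairwise Procrustes distance among the
repeats with the smallest pairwise Procrustes distance among distinct
specimens.  Digitization error is acceptable when every repeat pair is
closer than the closest pair of real individuals (ratio > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import ShapeDataset
from .procrustes import procrustes_distance


@dataclass
class ErrorAssessment:
    max_repeat_distance: float
    min_between_distance: float
    ratio: float  # min_between / max_repeat
    acceptable: bool

    def report(self) -> str:
        verdict = "acceptable" if self.acceptable else "NOT acceptable"
        return (
            "Intra-observer error assessment\n"
            f"  greatest distance among repeats      : {self.max_repeat_distance:.6g}\n"
            f"  smallest distance between specimens  : {self.min_between_distance:.6g}\n"
            f"  ratio (between / repeat)             : {self.ratio:.3g}\n"
            f"  verdict: digitization error is {verdict}\n"
        )


def _pairwise(coords: np.ndarray):
    for i, j in combinations(range(coords.shape[0]), 2):
        yield procrustes_distance(coords[i], coords[j])


def assess(repeats: ShapeDataset, specimens: ShapeDataset) -> ErrorAssessment:
    """Compare repeat-digitization scatter with between-specimen separation."""
    if len(repeats) < 2:
        raise ValueError("need >= 2 repeated digitizations")
    if len(specimens) < 2:
        raise ValueError("need >= 2 distinct specimens")
    rep = repeats.coords_array()
    spc = specimens.coords_array()
    max_repeat = max(_pairwise(rep))
    min_between = min(_pairwise(spc))
    ratio = np.inf if max_repeat == 0 else min_between / max_repeat
    return ErrorAssessment(
        max_repeat_distance=float(max_repeat),
        min_between_distance=float(min_between),
        ratio=float(ratio),
        acceptable=bool(ratio > 1),
    )
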