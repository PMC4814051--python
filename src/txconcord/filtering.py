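"""Expressed / inducible gene filter.

Microarrays estimate low-abundance transcripts poorly, so the gene-level
feature space is restricted to genes that exceed each array's own median
intensity on a minimum fraction of control arrays ("expressed") or treatment
arrays ("inducible"). The comparison is strict (>) and rank-based per array,
so the filter is invariant to any monotone per-array transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressedGeneSet:
    retained: list
    expressed: set
    inducible: set
    fraction: float

    def __post_init__(self) -> None:
        assert set(self.retained) == self.expressed | self.inducible


def expressed_gene_filter(intensities: IntensityMatrix, fraction: float = 0.10) -> ExpressedGeneSet:
    """Retain genes above the per-array median on >= ``fraction`` of control
    arrays (expressed) or of treatment arrays (inducible). The >= on the
    fraction is inclusive: 1 of 10 arrays passes at fraction 0.10.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    controls = intensities.arrays("control")
    treatments = intensities.arrays("treatment")
    if controls.shape[1] == 0 or treatments.shape[1] == 0:
        raise ValueError("need at least one control and one treatment array")

    def _passing(arm_frame) -> set:
        medians = arm_frame.median(axis=0)  # per-array median over features
        if (arm_frame.nunique(axis=0) == 1).any():
            logger.warning("all-constant array present; strict > retains nothing on it")
        above = arm_frame.gt(medians, axis=1)
        frac_above = above.mean(axis=1)
        return set(arm_frame.index[frac_above >= fraction])

    expressed = _passing(controls)
    inducible = _passing(treatments)
    retained = sorted(expressed | inducible)
    return ExpressedGeneSet(retained=retained, expressed=expressed, inducible=inducible,
                            fraction=fraction)
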