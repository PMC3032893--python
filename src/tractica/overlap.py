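"""Overlap statistics: population tractograms, Dice, proportion-of-volume.

The population tractogram of a seed cluster sums the cluster's tractograms
within each subject, binarises (> 0), and sums the binary maps across
subjects; thresholding it at a fraction f keeps voxels present in at least
ceil(f * n_subjects) subjects (so 50% of 38 subjects cuts at 19).

Dice uses the conventional 2|X n Y| / (|X| + |Y|); the proportion of
volume |IC n tract| / |tract| measures how much of the raw tractography a
component accounts for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import TractogramStack


@dataclass
class PopulationTractogram:
    subject_count_map: np.ndarray       # int volume, values in [0, S]
    n_subjects: int
    thresholds_applied: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.subject_count_map < 0) or np.any(
                self.subject_count_map > self.n_subjects):
            raise ValueError("subject counts must lie in [0, n_subjects]")


def population_tractogram(per_subject_stacks: list[TractogramStack],
                          significant_seeds: np.ndarray
                          ) -> PopulationTractogram:
    """Sum the tractograms of the significant seeds within each subject,
    binarise at > 0, and sum the binary maps across subjects."""
    sig = np.asarray(significant_seeds).astype(bool)
    if not sig.any():
        raise ValueError("empty significant seed set")
    ref = per_subject_stacks[0]
    if len(sig) != ref.n_seeds:
        raise ValueError("significant_seeds length does not match the "
                         "seed table")
    count = np.zeros(ref.grid_shape, dtype=int)
    for stack in per_subject_stacks:
        summed = stack.data[..., sig].sum(axis=-1)
        count += (summed > 0)
    return PopulationTractogram(subject_count_map=count,
                                n_subjects=len(per_subject_stacks))


def threshold_population(pop: PopulationTractogram,
                         fraction: float) -> np.ndarray:
    """Keep voxels present in at least ceil(fraction * n_subjects)
    subjects."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    cut = math.ceil(fraction * pop.n_subjects)
    return pop.subject_count_map >= cut


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X n Y| / (|X| + |Y|) between binary masks."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("mask shapes differ")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        raise ValueError("undefined Dice: both masks empty")
    return 2.0 * int(np.sum(x & y)) / (nx + ny)


def overlap_proportion(ic_mask: np.ndarray, tract_mask: np.ndarray) -> float:
    """|IC n tract| / |tract|: the proportion of the tractogram detected
    by the component."""
    ic = np.asarray(ic_mask).astype(bool)
    tract = np.asarray(tract_mask).astype(bool)
    if ic.shape != tract.shape:
        raise ValueError("mask shapes differ")
    nt = int(tract.sum())
    if nt == 0:
        raise ValueError("empty tract mask: proportion undefined")
    return int(np.sum(ic & tract)) / nt


def comparison_tables(ic_masks: dict[str, np.ndarray],
                      populations: dict[str, PopulationTractogram],
                      ica_seed_maps: dict[str, np.ndarray] | None = None,
                      hard_seed_maps: dict[str, np.ndarray] | None = None,
                      fractions: tuple[float, ...] = (0.25, 0.5, 0.75),
                      ) -> dict[str, pd.DataFrame]:
    """Assemble the study comparison tables.

    Returns ``dice``: per-ROI Dice between the thresholded component volume
    and the population tractogram at each population threshold;
    ``proportion``: per-ROI proportion of the population tractogram covered
    by the component; and (when both seed-space segmentations are given)
    ``hard_vs_ica``: per-ROI Dice between the ICA and winner-takes-all seed
    parcellations.  Missing ROIs yield NA rows.
    """
    cols = [f"t{int(round(f * 100))}" for f in fractions]
    regions = sorted(set(ic_masks) | set(populations))
    dice_rows, prop_rows = [], []
    for region in regions:
        drow: dict = {"region": region}
        prow: dict = {"region": region}
        ic = ic_masks.get(region)
        pop = populations.get(region)
        for f, c in zip(fractions, cols):
            if ic is None or pop is None:
                drow[c] = np.nan
                prow[c] = np.nan
                continue
            tract = threshold_population(pop, f)
            if not tract.any() or (not ic.any() and not tract.any()):
                drow[c] = np.nan
                prow[c] = np.nan
            else:
                drow[c] = dice(ic, tract) if (ic.any() or tract.any()) \
                    else np.nan
                prow[c] = overlap_proportion(ic, tract)
        dice_rows.append(drow)
        prop_rows.append(prow)
    tables = {
        "dice": pd.DataFrame(dice_rows, columns=["region"] + cols),
        "proportion": pd.DataFrame(prop_rows, columns=["region"] + cols),
    }
    if ica_seed_maps is not None and hard_seed_maps is not None:
        rows = []
        for region in sorted(set(ica_seed_maps) | set(hard_seed_maps)):
            a = ica_seed_maps.get(region)
            b = hard_seed_maps.get(region)
            if a is None or b is None or (not np.any(a) and not np.any(b)):
                val = np.nan
            else:
                val = dice(a, b)
            rows.append({"region": region, "dice": val})
        tables["hard_vs_ica"] = pd.DataFrame(rows,
                                             columns=["region", "dice"])
    return tables
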