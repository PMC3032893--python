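"""Tractogram stacks: assembly, downsampling and volumetric I/O.

A *tractogram* is the 3D visitation-count map produced by probabilistic
streamlines launched from one seed voxel.  A :class:`TractogramStack` holds
one such 3D volume per seed voxel of a subject, concatenated along a fourth
axis; a :class:`GroupStack` collects the per-subject stacks of one study,
which must share the grid, the seed table and the common-space tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd


def _default_affine(voxel_size_mm: float = 2.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class TractogramStack:
    """4D stack of per-seed tractograms for one subject.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, n_seeds)
        Non-negative visitation counts; volume ``v`` is the tractogram of
        seed ``seed_table[v]``.
    seed_table : ndarray, shape (n_seeds, 3)
        0-based voxel indices of the seeds, in the tracker's scan order.
    """

    data: np.ndarray
    seed_table: np.ndarray
    subject_id: str = ""
    space_tag: str = "phantom"
    affine: np.ndarray = field(default_factory=_default_affine)
    target_hits: np.ndarray | None = None   # (n_seeds, n_targets), tracker target mode
    target_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.seed_table = np.asarray(self.seed_table, dtype=int)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (X, Y, Z, n_seeds)")
        if self.seed_table.ndim != 2 or self.seed_table.shape[1] != 3:
            raise ValueError("seed_table must have shape (n_seeds, 3)")
        if self.data.shape[3] != len(self.seed_table):
            raise ValueError(
                f"n_seeds mismatch: data has {self.data.shape[3]} volumes, "
                f"seed_table has {len(self.seed_table)} entries"
            )
        if np.any(self.data < 0):
            raise ValueError("tractogram counts must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_seeds(self) -> int:
        return self.data.shape[3]


@dataclass
class GroupStack:
    """Per-subject tractogram stacks sharing grid, seed table and space."""

    subjects: list[TractogramStack]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("GroupStack needs at least one subject")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if s.grid_shape != ref.grid_shape:
                raise ValueError("all subjects must share the spatial grid")
            if not np.array_equal(s.seed_table, ref.seed_table):
                raise ValueError("all subjects must share the seed table")
            if s.space_tag != ref.space_tag:
                raise ValueError("all subjects must share the space tag")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def seed_table(self) -> np.ndarray:
        return self.subjects[0].seed_table

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.subjects[0].grid_shape


def concatenate(tractograms: Sequence, subject_id: str = "",
                space_tag: str = "phantom",
                affine: np.ndarray | None = None) -> TractogramStack:
    """Concatenate per-seed :class:`~tractica.tracking.Tractogram` objects
    into a 4D stack, in the order given (the tracker's scan order)."""
    if not tractograms:
        raise ValueError("nothing to concatenate")
    grid = tractograms[0].counts.shape
    seeds = []
    for t in tractograms:
        if t.counts.shape != grid:
            raise ValueError("grid mismatch between tractograms")
        seeds.append(tuple(int(i) for i in t.seed_index))
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seed indices in concatenation")
    data = np.stack([t.counts for t in tractograms], axis=-1)
    kwargs = {}
    if affine is not None:
        kwargs["affine"] = affine
    hits = [getattr(t, "target_hits", None) for t in tractograms]
    if all(h is not None for h in hits):
        names = tuple(sorted(hits[0]))
        kwargs["target_hits"] = np.array(
            [[h[n] for n in names] for h in hits], dtype=int)
        kwargs["target_names"] = names
    return TractogramStack(data=data, seed_table=np.array(seeds),
                           subject_id=subject_id, space_tag=space_tag,
                           **kwargs)


def _block_mean_axis(a: np.ndarray, axis: int, factor: int) -> np.ndarray:
    # partial trailing blocks are averaged over their actual size
    n = a.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(a, starts, axis=axis)
    lengths = np.diff(np.append(starts, n)).astype(float)
    shape = [1] * a.ndim
    shape[axis] = len(starts)
    return sums / lengths.reshape(shape)


def downsample(stack: TractogramStack, factor: int) -> TractogramStack:
    """Spatially downsample a stack by non-overlapping block means.

    The seed table is untouched: seeds stay indexed on the original grid.
    The mean (not the sum) is used so intensity scale is resolution
    independent; when all dimensions divide evenly the global mean is
    preserved exactly.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor > min(stack.grid_shape):
        raise ValueError(
            f"factor {factor} exceeds a grid dimension {stack.grid_shape}")
    if factor == 1:
        return stack
    out = stack.data.astype(float)
    for ax in range(3):
        out = _block_mean_axis(out, ax, factor)
    aff = stack.affine.copy()
    aff[:3, :3] *= factor
    return TractogramStack(data=out, seed_table=stack.seed_table.copy(),
                           subject_id=stack.subject_id,
                           space_tag=stack.space_tag, affine=aff,
                           target_hits=stack.target_hits,
                           target_names=stack.target_names)


# ---------------------------------------------------------------------------
# I/O

def save_volume(vol: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = _default_affine()
    nib.save(nib.Nifti1Image(np.asarray(vol), affine), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_stack(stack: TractogramStack, nifti_path: str | Path,
               table_path: str | Path) -> None:
    """Write the 4D counts as NIfTI and the seed table as TSV
    (columns volume_index, i, j, k; 0-based voxel indices)."""
    nib.save(nib.Nifti1Image(stack.data, stack.affine), str(nifti_path))
    df = pd.DataFrame(stack.seed_table, columns=["i", "j", "k"])
    df.insert(0, "volume_index", np.arange(len(df)))
    df.to_csv(table_path, sep="\t", index=False)


def load_stack(nifti_path: str | Path, table_path: str | Path,
               subject_id: str = "", space_tag: str = "phantom"
               ) -> TractogramStack:
    img = nib.load(str(nifti_path))
    df = pd.read_csv(table_path, sep="\t").sort_values("volume_index")
    return TractogramStack(data=np.asarray(img.dataobj),
                           seed_table=df[["i", "j", "k"]].to_numpy(),
                           subject_id=subject_id, space_tag=space_tag,
                           affine=np.asarray(img.affine))
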