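"""Brain parcellations: loading, exclusion rules, resampling and ROI reduction.

An atlas is a maximum-probability label image: each voxel carries one integer
region id (0 = background).  Feature extraction reduces a voxel map (Hurst
exponent map, modulated gray-matter map) to one value per retained region.
Exclusion rules mirror common practice for whole-brain parcellations, e.g.
dropping cerebellar regions or the brain stem before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

from .exceptions import AtlasFormatError, EmptyAtlasError, GridMismatchError

logger = logging.getLogger(__name__)

__all__ = ["AtlasDefinition", "load_atlas", "read_region_names", "roi_reduce"]


@dataclass
class AtlasDefinition:
    """A labeled parcellation grid plus region bookkeeping.

    Attributes
    ----------
    name : str
        Short atlas identifier used in feature names (e.g. ``"AAL-90"``).
    labels : np.ndarray
        3-D integer array of region ids, 0 meaning background.
    affine : np.ndarray
        4x4 voxel-to-world transform of ``labels``.
    region_ids : np.ndarray
        Strictly increasing ids retained for feature extraction.
    region_names : dict
        Region id -> human-readable name; defaults to ``"region_<id>"``.
    excluded_ids : list
        Ids removed before feature extraction (e.g. cerebellum, brain stem).
    """

    name: str
    labels: np.ndarray
    affine: np.ndarray
    region_ids: np.ndarray
    region_names: Mapping[int, str] = field(default_factory=dict)
    excluded_ids: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.region_ids = np.asarray(sorted(int(r) for r in self.region_ids), dtype=int)
        if self.region_ids.size == 0:
            raise EmptyAtlasError(f"atlas {self.name!r} retains no regions")
        if np.any(self.region_ids <= 0):
            raise AtlasFormatError("region ids must be positive integers")
        excluded = set(int(e) for e in self.excluded_ids)
        if excluded & set(self.region_ids.tolist()):
            raise AtlasFormatError("region_ids must not contain excluded ids")
        present = set(np.unique(self.labels).tolist())
        missing = [r for r in self.region_ids.tolist() if r not in present]
        if missing:
            raise AtlasFormatError(
                f"region ids absent from the label image: {missing[:10]}"
            )

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    def region_name(self, region_id: int) -> str:
        return self.region_names.get(region_id, f"region_{region_id}")

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def resampled_to(self, shape: tuple, affine: np.ndarray) -> "AtlasDefinition":
        """Nearest-neighbour resampling onto a target grid.

        Labels stay integral by construction.  Regions whose every voxel
        vanishes on the coarser grid are dropped with a warning (small
        structures can disappear when a 1 mm atlas is brought to 3 mm).
        """
        from nilearn.image import resample_img

        src = nib.Nifti1Image(self.labels.astype(np.int32), self.affine)
        out = resample_img(
            src,
            target_affine=affine,
            target_shape=tuple(int(s) for s in shape),
            interpolation="nearest",
            force_resample=True,
            copy_header=True,
        )
        new_labels = np.asarray(out.dataobj).astype(int)
        present = set(np.unique(new_labels).tolist())
        kept = [r for r in self.region_ids.tolist() if r in present]
        lost = [r for r in self.region_ids.tolist() if r not in present]
        if lost:
            logger.warning(
                "atlas %s: %d region(s) vanished during resampling and were "
                "dropped: %s",
                self.name,
                len(lost),
                lost,
            )
        if not kept:
            raise EmptyAtlasError(f"atlas {self.name!r}: resampling removed all regions")
        return AtlasDefinition(
            name=self.name,
            labels=new_labels,
            affine=np.asarray(affine, dtype=float),
            region_ids=np.asarray(kept, dtype=int),
            region_names=dict(self.region_names),
            excluded_ids=list(self.excluded_ids),
        )


def read_region_names(path: str | Path) -> dict[int, str]:
    """Read a two-column (id, name) TSV into a lookup dict."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", header=None, names=["id", "name"], comment="#")
    return {int(row.id): str(row.name) for row in frame.itertuples()}


def load_atlas(
    path: str | Path,
    exclusions: Iterable[int] = (),
    *,
    name: str | None = None,
    region_names: Mapping[int, str] | str | Path | None = None,
) -> AtlasDefinition:
    """Load a NIfTI label image and apply region exclusions.

    ``region_ids`` becomes the set of positive labels observed in the image
    minus ``exclusions``.  Non-integral voxel values are a format error; an
    exclusion list that removes every region is an empty-atlas error.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise AtlasFormatError(f"{path.name}: label image has non-integer values")
        data = rounded.astype(int)
    if data.min() < 0:
        raise AtlasFormatError(f"{path.name}: label image has negative values")
    observed = np.unique(data)
    observed = observed[observed > 0]
    excluded = sorted(int(e) for e in exclusions)
    retained = [int(r) for r in observed if int(r) not in set(excluded)]
    if not retained:
        raise EmptyAtlasError(f"{path.name}: all labels excluded")
    if isinstance(region_names, (str, Path)):
        region_names = read_region_names(region_names)
    atlas = AtlasDefinition(
        name=name or path.stem.replace(".nii", ""),
        labels=data.astype(int),
        affine=np.asarray(img.affine, dtype=float),
        region_ids=np.asarray(retained, dtype=int),
        region_names=dict(region_names or {}),
        excluded_ids=excluded,
    )
    logger.info(
        "atlas %s: %d labels observed, %d retained after exclusions",
        atlas.name,
        observed.size,
        atlas.n_regions,
    )
    return atlas


def roi_reduce(
    voxel_map: np.ndarray,
    atlas: AtlasDefinition,
    reducer: str = "mean",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Reduce a voxel map to one value per retained region.

    Parameters
    ----------
    voxel_map : np.ndarray
        3-D map on the same grid as ``atlas.labels``.
    reducer : {"mean", "sum"}
        Within-region reduction.
    mask : np.ndarray, optional
        Boolean analysis mask; voxels outside it are ignored.  A region with
        no voxels inside the mask yields NaN (flagged missing) and a warning.

    Returns
    -------
    np.ndarray
        Values ordered as ``atlas.region_ids`` (ascending label id).
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    if voxel_map.shape != atlas.labels.shape:
        raise GridMismatchError(
            f"voxel map shape {voxel_map.shape} != atlas grid {atlas.labels.shape}; "
            "resample the atlas first"
        )
    if reducer not in ("mean", "sum"):
        raise ValueError(f"unknown reducer {reducer!r}")
    labels = atlas.labels
    values = voxel_map
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != labels.shape:
            raise GridMismatchError("mask shape does not match atlas grid")
        labels = np.where(mask, labels, 0)
    flat_labels = labels.ravel()
    nmax = int(flat_labels.max()) + 1
    sums = np.bincount(flat_labels, weights=values.ravel(), minlength=nmax)
    counts = np.bincount(flat_labels, minlength=nmax)
    out = np.full(atlas.n_regions, np.nan)
    for i, rid in enumerate(atlas.region_ids):
        if rid >= nmax or counts[rid] == 0:
            logger.warning(
                "atlas %s: region %d has no voxels inside the mask; value set to NaN",
                atlas.name,
                rid,
            )
            continue
        out[i] = sums[rid] / counts[rid] if reducer == "mean" else sums[rid]
    return out
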