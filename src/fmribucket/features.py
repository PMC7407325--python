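"""Atlas-region voxel-count feature extraction from t-statistic volumes.

A subject-level t-map (the 2-back > 0-back working-memory contrast) is
thresholded at a fixed t-value and the surviving voxels are counted within
each region of an integer-labelled anatomical parcellation (an AAL-style
atlas).  The per-region counts, one row per subject, form the feature
matrix used by the downstream model build.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Default suprathreshold cut: t > 3.17, i.e. p < 0.001 uncorrected for the
#: study's degrees of freedom.  "Exceeding" is read strictly.
DEFAULT_T_THRESHOLD = 3.17


@dataclass
class AtlasVolume:
    """Integer-labelled parcellation on a regular grid.

    ``labels`` holds 0 for background and 1..R for regions; every voxel
    carries exactly one label.  ``region_table`` has one row per region
    (columns ``region_id``, ``name``, ``com_x``, ``com_y``, ``com_z`` with
    centers of mass in world/MNI mm).  ``affine`` maps voxel indices to
    world coordinates.
    """

    labels: np.ndarray
    region_table: pd.DataFrame
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D grid")
        present = set(np.unique(self.labels)) - {0}
        tabled = set(self.region_table["region_id"].tolist())
        if not present <= tabled:
            raise ValueError(f"labels {sorted(present - tabled)} missing from region_table")
        if self.region_table["region_id"].duplicated().any():
            raise ValueError("duplicate region_id in region_table")
        if self.region_table["name"].duplicated().any():
            raise ValueError("duplicate region name in region_table")

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def region_ids(self) -> list[int]:
        return self.region_table["region_id"].tolist()

    @property
    def region_names(self) -> list[str]:
        return self.region_table["name"].tolist()

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.labels.astype(np.int16), self.affine)


@dataclass
class VoxelStatMap:
    """One subject's 3-D t-value grid with its voxel-to-world affine."""

    t_values: np.ndarray
    affine: np.ndarray
    subject_id: str
    day: int = 1

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if self.t_values.ndim != 3:
            raise ValueError("t_values must be a 3-D grid")

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.t_values.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, path, subject_id: str, day: int = 1) -> "VoxelStatMap":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine, subject_id, day)


@dataclass
class FeatureTable:
    """Subjects x regions matrix of suprathreshold voxel counts.

    ``counts`` is indexed by subject id with one column per atlas region
    (atlas order); ``metadata`` is indexed identically and carries group,
    age, sex, BMI, day and any symptom-severity columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    region_ids: list[int] = field(default_factory=list)
    threshold_used: float = DEFAULT_T_THRESHOLD

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.counts.index]
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("feature counts must be non-negative")

    @property
    def n_subjects(self) -> int:
        return len(self.counts)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    def with_counts(self, counts: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(counts, self.metadata.copy(), list(self.region_ids), self.threshold_used)

    def to_tsv(self, counts_path, metadata_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t")


def threshold_map(stat_map: VoxelStatMap, t_thresh: float = DEFAULT_T_THRESHOLD) -> np.ndarray:
    """Binary mask of voxels whose t-value strictly exceeds ``t_thresh``.

    Missing (NaN) t-values never enter the mask; their number is logged so
    that silent data loss is visible.
    """
    if not np.isfinite(t_thresh):
        raise ValueError("t_thresh must be finite")
    t = stat_map.t_values
    if 0 in t.shape:
        raise ValueError(f"degenerate map shape {t.shape} for subject {stat_map.subject_id}")
    n_missing = int(np.isnan(t).sum())
    if n_missing:
        logger.warning(
            "subject %s: %d missing t-values treated as subthreshold",
            stat_map.subject_id,
            n_missing,
        )
    with np.errstate(invalid="ignore"):
        return t > t_thresh


def _resample_labels(atlas: AtlasVolume, target_shape, target_affine) -> np.ndarray:
    """Nearest-neighbour resampling of atlas labels onto a target grid.

    Labels are categorical, so order-0 interpolation in world space is the
    only meaningful resampling.  Voxels falling outside the atlas grid get
    background label 0.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    atlas_affine = np.asarray(atlas.affine, dtype=float)
    try:
        composite = np.linalg.inv(atlas_affine) @ target_affine
    except np.linalg.LinAlgError as err:
        raise ValueError("atlas affine is singular; cannot align grids") from err
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target_shape), indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    src = composite @ vox
    coords = src[:3]
    resampled = ndimage.map_coordinates(
        atlas.labels, coords, order=0, mode="constant", cval=0
    )
    return resampled.reshape(target_shape).astype(atlas.labels.dtype)


def count_voxels_by_region(
    mask: np.ndarray, atlas: AtlasVolume, mask_affine: np.ndarray | None = None
) -> np.ndarray:
    """Count suprathreshold voxels per atlas region.

    Returns a vector of length R following the atlas region-table order.
    Background voxels (label 0) are discarded.  If ``mask_affine`` is given
    and the grids differ, the atlas is resampled nearest-neighbour onto the
    mask grid first.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = atlas.labels
    if mask.shape != labels.shape or (
        mask_affine is not None and not np.allclose(mask_affine, atlas.affine)
    ):
        if mask_affine is None:
            raise ValueError(
                f"mask shape {mask.shape} does not match atlas {labels.shape} "
                "and no mask affine was provided for resampling"
            )
        labels = _resample_labels(atlas, mask.shape, mask_affine)
    region_ids = np.asarray(atlas.region_ids)
    hits = labels[mask]
    binned = np.bincount(hits, minlength=int(region_ids.max()) + 1)
    return binned[region_ids]


def build_feature_table(
    maps: list[VoxelStatMap],
    atlas: AtlasVolume,
    t_thresh: float = DEFAULT_T_THRESHOLD,
    metadata: pd.DataFrame | None = None,
) -> FeatureTable:
    """Threshold and count every map, assembling the subjects x regions table.

    One row per map, columns in atlas region-table order.  Subjects with no
    suprathreshold voxels anywhere are kept as all-zero rows (and logged):
    absence of activation is information, not missingness.
    """
    if not maps:
        raise ValueError("no t-maps provided; refusing to build an empty feature table")
    days = {m.day for m in maps}
    if len(days) > 1:
        raise ValueError(f"maps span multiple days {sorted(days)}; build one table per day")
    ids = [m.subject_id for m in maps]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids for one day: {dupes}")
    if metadata is not None:
        missing = set(ids) - set(metadata.index)
        if missing:
            raise ValueError(f"subjects absent from metadata: {sorted(missing)}")

    rows = np.empty((len(maps), atlas.n_regions), dtype=np.int64)
    for i, m in enumerate(maps):
        mask = threshold_map(m, t_thresh)
        rows[i] = count_voxels_by_region(mask, atlas, mask_affine=m.affine)
        if rows[i].sum() == 0:
            logger.info("subject %s has zero suprathreshold voxels; kept as all-zero row", m.subject_id)

    counts = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=atlas.region_names)
    if metadata is None:
        metadata = pd.DataFrame(index=counts.index)
        metadata["day"] = maps[0].day
    else:
        metadata = metadata.loc[counts.index].copy()
        if "day" not in metadata.columns:
            metadata["day"] = maps[0].day
    return FeatureTable(counts, metadata, atlas.region_ids, t_thresh)
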