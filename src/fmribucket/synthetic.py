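"""Synthetic two-group cohort generator with planted regional effects.

The study data this pipeline was designed for (task-fMRI t-maps from a
Gulf War illness and a chronic fatigue syndrome cohort) are not publicly
deposited, so the generator emulates their statistical structure: an
atlas-like parcellation, per-subject suprathreshold voxel counts per
region drawn from an overdispersed count model, a standardized mean shift
planted in chosen regions for one group, demographic covariates matched
to the study's cohort table, and symptom-severity scores linearly coupled
to region counts.

Counts are drawn negative-binomial (non-negative integers, overdispersed
relative to Poisson); in "maps" mode each region of the subject's t-volume
receives exactly the drawn number of voxels with t in (3.2, 8.0) and all
other voxels t in (-2, 3.0), so extraction at the study threshold t > 3.17
recovers the latent counts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AtlasVolume, FeatureTable, VoxelStatMap

logger = logging.getLogger(__name__)

GROUP_A = "CFS"  # positive class throughout the pipeline
GROUP_B = "GWI"

#: The nine symptom-severity items of the study's cohort table (0-4 scale).
SYMPTOM_NAMES = [
    "fatigue",
    "memory_concentration",
    "sore_throat",
    "sore_lymph_nodes",
    "muscle_pain",
    "joint_pain",
    "headaches",
    "sleep",
    "exertional_exhaustion",
]

#: Demographics by group: age and BMI mean/SD, proportion male.
DEFAULT_COVARIATE_MODEL = {
    GROUP_A: {"age": (47.74, 16.46), "bmi": (26.20, 4.52), "male_prop": 0.263},
    GROUP_B: {"age": (46.9, 7.8), "bmi": (29.6, 5.6), "male_prop": 0.738},
}

DEFAULT_EFFECT_REGIONS = (10, 33, 56, 79, 102)


def _default_symptom_coupling(n_regions: int, effect_regions) -> np.ndarray:
    """Each symptom loads on one planted region, cycling through them."""
    w = np.zeros((len(SYMPTOM_NAMES), n_regions))
    if effect_regions:
        for i in range(len(SYMPTOM_NAMES)):
            region = effect_regions[i % len(effect_regions)]
            w[i, region - 1] = 1.0
    return w


@dataclass
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 38 CFS (group a) vs 80 GWI
    (group b) subjects, 117 atlas regions, a 24x24x24 test grid, baseline
    mean of 20 suprathreshold voxels per region with negative-binomial
    dispersion 8, and a standardized shift of 1.5 planted in five regions
    of the GWI group.
    """

    n_group_a: int = 38
    n_group_b: int = 80
    n_regions: int = 117
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    baseline_count_mean: float | np.ndarray = 20.0
    dispersion: float = 8.0
    effect_regions: tuple[int, ...] = DEFAULT_EFFECT_REGIONS
    effect_size: float = 1.5
    covariate_model: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_COVARIATE_MODEL.items()
    })
    symptom_coupling: np.ndarray | None = None
    symptom_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if np.any(np.asarray(self.baseline_count_mean) <= 0):
            raise ValueError("baseline_count_mean must be positive")
        bad = [r for r in self.effect_regions if not 1 <= r <= self.n_regions]
        if bad:
            raise ValueError(f"effect regions {bad} outside 1..{self.n_regions}")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def region_means(self) -> np.ndarray:
        mu = np.broadcast_to(
            np.asarray(self.baseline_count_mean, dtype=float), (self.n_regions,)
        ).copy()
        return mu

    def coupling_matrix(self) -> np.ndarray:
        if self.symptom_coupling is not None:
            w = np.asarray(self.symptom_coupling, dtype=float)
            if w.shape[1] != self.n_regions:
                raise ValueError(
                    f"symptom_coupling has {w.shape[1]} columns, expected {self.n_regions}"
                )
            return w
        return _default_symptom_coupling(self.n_regions, self.effect_regions)


@dataclass
class SyntheticCohort:
    """Generator output: latent counts (always), t-maps (``maps`` mode only)."""

    table: FeatureTable
    metadata: pd.DataFrame
    maps: list[VoxelStatMap] | None = None

    @property
    def latent_counts(self) -> pd.DataFrame:
        return self.table.counts


def generate_atlas(n_regions: int, grid_shape=(24, 24, 24), seed: int = 0) -> AtlasVolume:
    """Partition an ellipsoidal in-brain mask into contiguous labelled blocks.

    A stand-in for an anatomical parcellation: the in-mask voxels, taken in
    scan order, are cut into ``n_regions`` consecutive runs of near-equal
    size, giving a deterministic partition (each in-mask voxel carries
    exactly one label).  The seed permutes which block receives which
    region id.  The affine places 2 mm isotropic voxels centred on the
    world origin.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 1 for s in grid_shape):
        raise ValueError(f"grid_shape must be 3 positive ints, got {grid_shape}")

    shape = np.array(grid_shape)
    center = (shape - 1) / 2.0
    semi = np.maximum(shape * 0.45, 0.5)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    r2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    mask = r2 <= 1.0
    n_in = int(mask.sum())
    if n_regions > n_in:
        raise ValueError(
            f"cannot fit {n_regions} regions into a mask of {n_in} voxels "
            f"on grid {grid_shape}"
        )

    flat_idx = np.flatnonzero(mask.ravel())
    blocks = np.array_split(flat_idx, n_regions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_regions)
    labels = np.zeros(int(np.prod(shape)), dtype=np.int32)
    for block, rid in zip(blocks, order + 1):
        labels[block] = rid
    labels = labels.reshape(grid_shape)

    voxel_mm = 2.0
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -center * voxel_mm

    rows = []
    width = max(3, len(str(n_regions)))
    for rid in range(1, n_regions + 1):
        vox = np.argwhere(labels == rid)
        com_vox = vox.mean(axis=0)
        com_mm = affine[:3, :3] @ com_vox + affine[:3, 3]
        rows.append(
            {
                "region_id": rid,
                "name": f"Region_{rid:0{width}d}",
                "com_x": com_mm[0],
                "com_y": com_mm[1],
                "com_z": com_mm[2],
                "n_voxels": len(vox),
            }
        )
    return AtlasVolume(labels, pd.DataFrame(rows), affine)


def _draw_counts(spec: SyntheticCohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent counts for all subjects (group a rows first), plus group labels.

    Negative binomial with mean mu and shape (dispersion) k, so
    Var = mu + mu^2/k.  Group b means are shifted upward by
    effect_size * SD(baseline) in the planted effect regions.
    """
    k = spec.dispersion
    mu_a = spec.region_means()
    sd_a = np.sqrt(mu_a + mu_a**2 / k)
    mu_b = mu_a.copy()
    for r in spec.effect_regions:
        mu_b[r - 1] += spec.effect_size * sd_a[r - 1]

    def draw(mu: np.ndarray, n: int) -> np.ndarray:
        p = k / (k + mu)
        return rng.negative_binomial(k, p[None, :], size=(n, spec.n_regions))

    counts = np.vstack([draw(mu_a, spec.n_group_a), draw(mu_b, spec.n_group_b)])
    groups = np.array([GROUP_A] * spec.n_group_a + [GROUP_B] * spec.n_group_b)
    return counts, groups


def _draw_metadata(spec: SyntheticCohortSpec, groups: np.ndarray, rng: np.random.Generator,
                   subject_ids: list[str], day: int) -> pd.DataFrame:
    rows = []
    for g in groups:
        m = spec.covariate_model[g]
        rows.append(
            {
                "group": g,
                "age": float(np.clip(rng.normal(*m["age"]), 18.0, 90.0)),
                "bmi": float(np.clip(rng.normal(*m["bmi"]), 15.0, 60.0)),
                "sex": "M" if rng.random() < m["male_prop"] else "F",
                "day": day,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(subject_ids, name="subject_id"))


def generate_cohort(
    spec: SyntheticCohortSpec,
    atlas: AtlasVolume | None = None,
    mode: str = "table",
    day: int = 1,
) -> SyntheticCohort:
    """Draw a synthetic cohort as a feature table or as full t-map volumes.

    In ``"table"`` mode the latent per-region counts are returned directly
    as a :class:`FeatureTable`.  In ``"maps"`` mode each subject gets a 3-D
    t-volume in which exactly the latent count of voxels per region lies
    strictly above the t > 3.17 extraction threshold, so the downstream
    featurizer reproduces the latent table exactly.  Counts exceeding a
    region's voxel capacity are clipped (with a log message) and the
    clipped value recorded as the latent count.
    """
    if mode not in ("table", "maps"):
        raise ValueError(f"mode must be 'table' or 'maps', got {mode!r}")
    if atlas is None:
        atlas = generate_atlas(spec.n_regions, spec.grid_shape, seed=spec.seed)
    if atlas.n_regions != spec.n_regions:
        raise ValueError(
            f"atlas has {atlas.n_regions} regions but spec expects {spec.n_regions}"
        )
    if mode == "maps" and tuple(atlas.labels.shape) != tuple(spec.grid_shape):
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match spec grid {spec.grid_shape}"
        )

    rng = np.random.default_rng(spec.seed)
    counts, groups = _draw_counts(spec, rng)

    n_a = spec.n_group_a
    subject_ids = [f"{GROUP_A}_{i + 1:03d}" for i in range(n_a)] + [
        f"{GROUP_B}_{i + 1:03d}" for i in range(spec.n_group_b)
    ]
    metadata = _draw_metadata(spec, groups, rng, subject_ids, day)

    maps = None
    if mode == "maps":
        capacities = atlas.region_table.set_index("region_id")["n_voxels"]
        cap = capacities.loc[atlas.region_ids].to_numpy()
        over = counts > cap[None, :]
        if over.any():
            logger.warning(
                "%d latent counts exceeded region capacity and were clipped", int(over.sum())
            )
            counts = np.minimum(counts, cap[None, :])
        region_voxels = {
            rid: np.argwhere(atlas.labels == rid) for rid in atlas.region_ids
        }
        maps = []
        for s, sid in enumerate(subject_ids):
            t = rng.uniform(-2.0, 3.0, size=atlas.labels.shape)
            for j, rid in enumerate(atlas.region_ids):
                c = int(counts[s, j])
                if c == 0:
                    continue
                vox = region_voxels[rid]
                pick = vox[rng.choice(len(vox), size=c, replace=False)]
                t[pick[:, 0], pick[:, 1], pick[:, 2]] = rng.uniform(3.2, 8.0, size=c)
            maps.append(VoxelStatMap(t, atlas.affine.copy(), sid, day))

    counts_df = pd.DataFrame(
        counts, index=pd.Index(subject_ids, name="subject_id"), columns=atlas.region_names
    )
    table = FeatureTable(counts_df, metadata, atlas.region_ids)
    cohort = SyntheticCohort(table, metadata, maps)

    symptoms = generate_symptoms(table, spec, rng=rng)
    table.metadata = table.metadata.join(symptoms)
    cohort.metadata = table.metadata
    return cohort


def generate_symptoms(
    counts: FeatureTable,
    spec: SyntheticCohortSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nine symptom-severity scores per subject on the 0-4 scale.

    Each score is a linear combination of z-scored region counts plus
    Gaussian noise, affinely mapped into [0, 4] around the scale midpoint.
    The map rescales by the largest absolute raw score, so the clip never
    bites and monotone relationships between a coupled region and its
    symptom are preserved exactly; zero coupling with zero noise yields the
    constant midpoint 2.0.
    """
    w = spec.coupling_matrix()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    x = counts.counts.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    raw = z @ w.T
    if spec.symptom_noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.symptom_noise_sd, size=raw.shape)
    peak = np.abs(raw).max()
    if peak > 0:
        scores = 2.0 + 2.0 * raw / peak
    else:
        scores = np.full_like(raw, 2.0)
    scores = np.clip(scores, 0.0, 4.0)
    return pd.DataFrame(scores, index=counts.counts.index, columns=SYMPTOM_NAMES)
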