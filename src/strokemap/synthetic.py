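"""Synthetic stroke cohort generator with a planted three-component structure.

The generator emulates the statistical shape of an acute-stroke bedside
battery (10 OCS-like subtests plus 15 NIHSS-like items) paired with binary
lesion masks on a common grid:

* lesions are single connected regions grown inside one vascular territory
  of one hemisphere, with log-normal volumes;
* three planted voxel weight maps (two left-lateralized, one
  right-lateralized) convert lesions into latent severities;
* subtest scores are noisy, integer-rounded functions of those severities,
  with a configurable fraction of subjects at ceiling, producing the
  long-tailed, zero-inflated deficit distributions typical of such
  batteries.

Everything is reproducible from a single seed; per-subject random substreams
are derived from (seed, subject index) so results do not depend on
generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .images import LesionCohort, LesionImage, write_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Atlas",
    "default_battery",
    "make_atlas",
    "sample_lesion",
    "behavioural_scores",
    "generate_cohort",
    "write_cohort",
]

# Pooled territory codes: per-hemisphere labels are 1..3 (left) and 4..6
# (right); label % 3 identifies the pooled territory.
TERRITORY_NAMES = ("deep", "anterior_superior", "posterior_inferior")
LEFT_LABELS = (1, 2, 3)
RIGHT_LABELS = (4, 5, 6)

# Severities are rescaled by this quantile of the nonzero lesion-map
# overlaps (then clipped to 1): lesions destroying most of a planted region
# saturate the corresponding deficit.
SEVERITY_SATURATION_QUANTILE = 0.9


def default_battery() -> tuple[list[str], np.ndarray, np.ndarray]:
    """Default 25-subtest battery: names, integer maxima, planted loadings.

    The loading matrix has a three-block structure mirroring the canonical
    post-stroke components: a language/number/praxis/memory block (planted on
    left cortical damage), a left-motor/visuospatial-neglect block (right
    hemisphere), and a right-motor block (left deep/subcortical damage).
    """
    rows = [
        # name,                     max, (c1,   c2,   c3)
        ("ocs_picture_naming",        4, (0.85, 0.00, 0.00)),
        ("ocs_semantics",             3, (0.80, 0.00, 0.00)),
        ("ocs_sentence_reading",     15, (0.80, 0.00, 0.00)),
        ("ocs_orientation",           4, (0.60, 0.10, 0.00)),
        ("ocs_recall_recognition",    4, (0.70, 0.00, 0.00)),
        ("ocs_episodic_memory",       4, (0.60, 0.10, 0.00)),
        ("ocs_number_writing",        3, (0.75, 0.00, 0.00)),
        ("ocs_calculation",           4, (0.80, 0.00, 0.00)),
        ("ocs_praxis",               12, (0.70, 0.00, 0.10)),
        ("ocs_heart_accuracy",       50, (0.15, 0.60, 0.00)),
        ("nihss_loc",                 3, (0.20, 0.20, 0.20)),
        ("nihss_loc_questions",       2, (0.50, 0.10, 0.00)),
        ("nihss_loc_commands",        2, (0.50, 0.10, 0.00)),
        ("nihss_gaze",                2, (0.00, 0.60, 0.00)),
        ("nihss_visual_fields",       3, (0.10, 0.60, 0.00)),
        ("nihss_facial_palsy",        3, (0.10, 0.40, 0.20)),
        ("nihss_motor_arm_left",      4, (0.00, 0.85, 0.00)),
        ("nihss_motor_arm_right",     4, (0.00, 0.00, 0.85)),
        ("nihss_motor_leg_left",      4, (0.00, 0.80, 0.00)),
        ("nihss_motor_leg_right",     4, (0.00, 0.00, 0.80)),
        ("nihss_ataxia",              2, (0.00, 0.10, 0.40)),
        ("nihss_sensory",             2, (0.00, 0.50, 0.10)),
        ("nihss_language",            3, (0.80, 0.00, 0.00)),
        ("nihss_dysarthria",          2, (0.20, 0.00, 0.50)),
        ("nihss_inattention",         2, (0.00, 0.75, 0.00)),
    ]
    names = [r[0] for r in rows]
    maxima = np.array([r[1] for r in rows], dtype=float)
    loadings = np.array([r[2] for r in rows], dtype=float)
    return names, maxima, loadings


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 2.0
    n_subjects: int = 200
    left_fraction: float = 0.5
    volume_log_mean: float = float(np.log(500.0))  # log-voxels; median 500
    volume_log_sd: float = 0.8
    subtest_names: list[str] = field(default_factory=lambda: default_battery()[0])
    subtest_maxima: np.ndarray = field(default_factory=lambda: default_battery()[1])
    loading_matrix: np.ndarray = field(default_factory=lambda: default_battery()[2])
    noise_sd: float = 0.1
    ceiling_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.subtest_maxima = np.asarray(self.subtest_maxima, dtype=float)
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ConfigError("grid_shape must be three integers, all >= 8")
        if self.voxel_size_mm <= 0:
            raise ConfigError("voxel_size_mm must be positive")
        if self.n_subjects < 10:
            raise ConfigError("n_subjects must be >= 10 for downstream fits")
        if not 0.0 <= self.left_fraction <= 1.0:
            raise ConfigError("left_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not 0.0 <= self.ceiling_fraction <= 1.0:
            raise ConfigError("ceiling_fraction must lie in [0, 1]")
        L = self.loading_matrix
        if L.ndim != 2 or L.shape[1] != 3:
            raise ConfigError("loading_matrix must be subtests x 3")
        if L.shape[0] != len(self.subtest_names) or L.shape[0] != len(self.subtest_maxima):
            raise ConfigError("loading_matrix rows must match subtest names/maxima")
        if ((L != 0).sum(axis=0) < 2).any():
            raise ConfigError("each loading_matrix column needs >= 2 nonzero entries")
        if (self.subtest_maxima <= 0).any():
            raise ConfigError("subtest maxima must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["subtest_maxima"] = self.subtest_maxima.tolist()
        d["loading_matrix"] = self.loading_matrix.tolist()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class Atlas:
    """Territory label image plus compartment masks on one grid."""

    labels: np.ndarray          # 0 background, 1..6 = 3 territories x 2 hemispheres
    cortical_mask: np.ndarray
    subcortical_mask: np.ndarray
    brain_mask: np.ndarray
    affine: np.ndarray


@dataclass
class GroundTruth:
    planted_maps: np.ndarray        # 3 x grid, true lesion->severity weights
    latent_severities: np.ndarray   # n_subjects x 3, rescaled to [0, 1]
    atlas: Atlas


def _grid_affine(grid_shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """RAS affine centred on the grid, so world x < 0 is the left hemisphere."""
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size_mm
    affine[:3, 3] = -voxel_size_mm * (np.array(grid_shape) - 1) / 2.0
    return affine


def make_atlas(grid_shape: tuple[int, int, int], voxel_size_mm: float = 2.0) -> Atlas:
    """Build a deterministic 6-label vascular-territory atlas.

    The brain is the ellipsoid inscribed in the grid. Per hemisphere, a deep
    central core (subcortical) is surrounded by a shell (cortical) split into
    anterior-superior and posterior-inferior territories. Midline voxels
    (world x == 0) are excluded so every territory is strictly lateralized.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 8 for s in grid_shape):
        raise ConfigError("grid_shape must be three integers, all >= 8")
    nx, ny, nz = grid_shape
    axes = [(np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0) for n in grid_shape]
    ux, uy, uz = np.meshgrid(*axes, indexing="ij")
    r2 = ux**2 + uy**2 + uz**2
    brain = r2 <= 1.0
    brain &= ux != 0.0  # drop exact-midline voxels (odd nx only)

    deep = brain & (r2 <= 0.55**2)
    shell = brain & ~deep
    ant_sup = shell & (uy + uz > 0)
    post_inf = shell & ~ant_sup
    left = ux < 0

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[deep & left] = 1
    labels[ant_sup & left] = 2
    labels[post_inf & left] = 3
    labels[deep & ~left] = 4
    labels[ant_sup & ~left] = 5
    labels[post_inf & ~left] = 6

    for lab in range(1, 7):
        if not (labels == lab).any():
            raise ConfigError(f"grid {grid_shape} too small: territory {lab} is empty")

    return Atlas(
        labels=labels,
        cortical_mask=np.isin(labels, (2, 3, 5, 6)),
        subcortical_mask=np.isin(labels, (1, 4)),
        brain_mask=labels > 0,
        affine=_grid_affine(grid_shape, voxel_size_mm),
    )


_NEIGHBOUR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def sample_lesion(
    atlas: Atlas | np.ndarray,
    territory_label: int,
    target_volume: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow one 6-connected lesion inside a territory by random frontier expansion.

    Growth starts at a uniformly random seed voxel of the territory and adds
    uniformly random frontier voxels until ``target_volume`` voxels are
    reached (or the territory is exhausted), yielding compact but irregular
    connected lesions.
    """
    labels = atlas.labels if isinstance(atlas, Atlas) else np.asarray(atlas)
    region = labels == territory_label
    n_region = int(region.sum())
    if n_region == 0:
        raise ValidationError(f"territory label {territory_label} is empty or absent")
    if target_volume < 1:
        raise ValidationError("target_volume must be >= 1")
    target = min(int(target_volume), n_region)
    if target == n_region:
        return region.copy()

    shape = labels.shape
    region_flat = region.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    coords = np.argwhere(region)
    seed_voxel = coords[rng.integers(len(coords))]
    seed_flat = int(seed_voxel @ strides)

    grown = {seed_flat}
    # frontier kept as list + membership set; random removal by swap-pop
    frontier: list[int] = []
    in_frontier: set[int] = set()

    def push_neighbours(flat: int) -> None:
        i, j, k = np.unravel_index(flat, shape)
        for di, dj, dk in _NEIGHBOUR_OFFSETS:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                nf = int(ni * strides[0] + nj * strides[1] + nk)
                if region_flat[nf] and nf not in grown and nf not in in_frontier:
                    frontier.append(nf)
                    in_frontier.add(nf)

    push_neighbours(seed_flat)
    while len(grown) < target and frontier:
        j = int(rng.integers(len(frontier)))
        frontier[j], frontier[-1] = frontier[-1], frontier[j]
        v = frontier.pop()
        in_frontier.discard(v)
        grown.add(v)
        push_neighbours(v)

    mask = np.zeros(labels.size, dtype=bool)
    mask[list(grown)] = True
    return mask.reshape(shape)


def _planted_maps(atlas: Atlas) -> np.ndarray:
    """Three smooth positive weight maps with the canonical lateralization.

    Component 1: left cortical shell; component 2: right hemisphere;
    component 3: left deep territory. Each map is a Gaussian bump centred on
    its support's centroid, zero outside the support.
    """
    supports = [
        np.isin(atlas.labels, (2, 3)),       # left cortical
        np.isin(atlas.labels, (4, 5, 6)),    # right hemisphere
        atlas.labels == 1,                   # left deep
    ]
    maps = np.zeros((3,) + atlas.labels.shape)
    for c, supp in enumerate(supports):
        coords = np.argwhere(supp).astype(float)
        centroid = coords.mean(axis=0)
        d2 = ((coords - centroid) ** 2).sum(axis=1)
        sigma2 = max(d2.mean(), 1.0)
        maps[c][supp] = np.exp(-d2 / (2.0 * sigma2))
    return maps


def behavioural_scores(
    lesions: np.ndarray | list[np.ndarray],
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the battery table from lesions and planted maps.

    Latent severity ``s_ic`` is the overlap of lesion i with planted map c,
    rescaled to [0, 1] by the cohort maximum. The noiseless deficit of
    subtest t is ``loadings[t] . s_i`` shifted down by its
    ``ceiling_fraction`` cohort quantile (so that fraction of subjects sits
    exactly at ceiling), then Gaussian noise is added, the result clipped to
    [0, 1], converted to a raw score and rounded (half away from zero) on
    the subtest's integer scale.

    Also updates ``ground_truth.latent_severities`` in place.
    """
    stack = np.stack([np.asarray(m, dtype=bool) for m in lesions])
    n = stack.shape[0]
    if stack.shape[1:] != ground_truth.planted_maps.shape[1:]:
        raise ValidationError("lesions are not aligned to the ground-truth grid")
    L = config.loading_matrix
    p = len(config.subtest_names)
    if L.shape[0] != p:
        raise ValidationError("loading_matrix rows must equal number of subtests")

    flat = stack.reshape(n, -1).astype(float)
    maps = ground_truth.planted_maps.reshape(3, -1)
    sev = flat @ maps.T                                  # n x 3 raw overlaps
    for c in range(sev.shape[1]):
        nonzero = sev[:, c][sev[:, c] > 0]
        if nonzero.size:
            # saturating rescale: deficits plateau once a large share of the
            # planted region is destroyed, so severities spread over [0, 1]
            # instead of bunching near zero under long-tailed lesion volumes
            sev[:, c] = np.clip(sev[:, c] / np.quantile(nonzero, SEVERITY_SATURATION_QUANTILE), 0.0, 1.0)
    ground_truth.latent_severities = sev

    deficit0 = sev @ L.T                                 # n x p, noiseless
    q = np.quantile(deficit0, config.ceiling_fraction, axis=0)
    deficit = deficit0 - q
    if config.noise_sd > 0:
        deficit = deficit + rng.normal(0.0, config.noise_sd, size=deficit.shape)
    deficit = np.clip(deficit, 0.0, 1.0)

    maxima = config.subtest_maxima
    raw = maxima * (1.0 - deficit)
    scores = np.floor(raw + 0.5)                         # round half away from zero (raw >= 0)
    scores = np.clip(scores, 0.0, maxima)

    table = pd.DataFrame(scores, columns=config.subtest_names)
    table.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(n)])
    return table


def generate_cohort(
    config: SimulationConfig,
) -> tuple[LesionCohort, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort: lesions, battery table, ground truth."""
    config.validate()
    atlas = make_atlas(config.grid_shape, config.voxel_size_mm)
    truth = GroundTruth(
        planted_maps=_planted_maps(atlas),
        latent_severities=np.zeros((config.n_subjects, 3)),
        atlas=atlas,
    )

    images = []
    for i in range(config.n_subjects):
        rng_i = np.random.default_rng([config.seed, i])
        is_left = rng_i.random() < config.left_fraction
        territory = int(rng_i.choice(LEFT_LABELS if is_left else RIGHT_LABELS))
        volume = max(1, int(round(rng_i.lognormal(config.volume_log_mean, config.volume_log_sd))))
        mask = sample_lesion(atlas, territory, volume, rng_i)
        images.append(LesionImage(mask=mask, affine=atlas.affine, subject_id=f"sub-{i:04d}"))

    cohort = LesionCohort(images=images, brain_mask=atlas.brain_mask)
    noise_rng = np.random.default_rng([config.seed, 10**6])
    battery = behavioural_scores([im.mask for im in images], truth, config, noise_rng)
    logger.info(
        "generated cohort: n=%d, median volume=%d voxels",
        len(cohort),
        int(np.median([im.n_voxels for im in images])),
    )
    return cohort, battery, truth


def write_cohort(
    cohort: LesionCohort,
    battery: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    outdir: str | Path,
) -> Path:
    """Write the cohort to disk in the pipeline's on-disk layout.

    Layout: ``lesions/<subject>.nii.gz`` + ``manifest.csv``; territory atlas
    and compartment masks; ``battery.csv`` + ``maxima.csv``; planted maps and
    latent severities; the config as YAML. Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "lesions").mkdir(parents=True, exist_ok=True)
    aff = cohort.affine
    rows = []
    for im in cohort.images:
        rel = f"lesions/{im.subject_id}.nii.gz"
        write_mask(im.mask, aff, outdir / rel)
        rows.append({"subject_id": im.subject_id, "path": rel})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)

    atlas = truth.atlas
    write_mask(atlas.labels, aff, outdir / "territory_atlas.nii.gz", dtype=np.int16)
    write_mask(atlas.cortical_mask, aff, outdir / "cortical_mask.nii.gz")
    write_mask(atlas.subcortical_mask, aff, outdir / "subcortical_mask.nii.gz")
    write_mask(atlas.brain_mask, aff, outdir / "brain_mask.nii.gz")
    for c in range(3):
        write_mask(truth.planted_maps[c], aff, outdir / f"planted_map_{c + 1}.nii.gz", dtype=np.float32)

    battery.to_csv(outdir / "battery.csv", index=False)
    pd.DataFrame(
        {"subtest": config.subtest_names, "maximum": config.subtest_maxima}
    ).to_csv(outdir / "maxima.csv", index=False)
    sev = pd.DataFrame(truth.latent_severities, columns=["severity_1", "severity_2", "severity_3"])
    sev.insert(0, "subject_id", cohort.subject_ids)
    sev.to_csv(outdir / "latent_severities.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    return outdir / "manifest.csv"
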