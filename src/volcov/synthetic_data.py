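"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a neonatal volumetry study in which the same cohort
is preprocessed by three skull-stripping workflows: a BET-like automatic
workflow whose volumes run systematically small, an iBEAT-like automatic
workflow that inflates skull-base-adjacent regions (cerebellum, inferior
temporal, fusiform, parahippocampal, entorhinal), and a manually corrected
reference workflow taken as unbiased.

Generative model
----------------
Latent regional volumes are multivariate log-normal: a subject draws a
64-vector of standard normals with an exchangeable block-correlation
structure (``n_modules`` equally sized modules, correlation
``within_module_corr`` inside a module and ``between_module_corr`` across
modules), which is then mapped per region to a log-normal with the exact
requested mean and standard deviation on the volume scale.  Log-normality
guarantees positivity and makes workflow biases act multiplicatively.  The
three workflow tables share the same latent draw — the per-region bias
vectors are the only systematic difference — and repeated measurements add
independent zero-mean Gaussian noise on the volume scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core_data import RegionAtlas, RegistrationFixture, VolumeTable, load_region_atlas

__all__ = [
    "CohortConfig",
    "DEFAULT_REGION_MEANS",
    "SKULL_BASE_REGIONS",
    "WORKFLOWS",
    "default_region_means",
    "default_workflow_biases",
    "block_correlation_matrix",
    "generate_cohort",
    "generate_repeats",
    "generate_registration_fixture",
]

WORKFLOWS = ("BET", "iBEAT", "iBEAT_corrected")

#: regions adjacent to the skull base, where imperfect stripping leaves
#: residual tissue and inflates the automatic iBEAT-like volumes
SKULL_BASE_REGIONS = (
    "Cerebellar hemisphere",
    "Inferior temporal gyrus",
    "Fusiform gyrus",
    "Parahippocampal gyrus",
    "Entorhinal cortex",
)

# Order-of-magnitude plausible mean volumes (mm³) per structure; constants
# are deliberately round and make no claim of matching real neonatal
# volumetry — only the relative scale matters to the pipeline.
DEFAULT_REGION_MEANS: dict[str, float] = {
    "Thalamus": 4000.0,
    "Putamen": 2200.0,
    "Globus pallidus": 900.0,
    "Caudate nucleus": 1800.0,
    "Superior frontal gyrus": 9000.0,
    "Middle frontal gyrus": 7500.0,
    "Inferior frontal gyrus": 5500.0,
    "Medial fronto-orbital gyrus": 2500.0,
    "Lateral fronto-orbital gyrus": 2200.0,
    "Gyrus rectus": 1200.0,
    "Precentral gyrus": 6000.0,
    "Postcentral gyrus": 5000.0,
    "Superior parietal gyrus": 5500.0,
    "Precuneus": 4500.0,
    "Cingular gyrus": 6500.0,
    "Supramarginal gyrus": 4000.0,
    "Angular gyrus": 4000.0,
    "Superior temporal gyrus": 6000.0,
    "Middle temporal gyrus": 6500.0,
    "Inferior temporal gyrus": 5000.0,
    "Fusiform gyrus": 4000.0,
    "Parahippocampal gyrus": 2000.0,
    "Entorhinal cortex": 800.0,
    "Superior occipital gyrus": 2500.0,
    "Middle occipital gyrus": 4500.0,
    "Inferior occipital gyrus": 2500.0,
    "Cuneus": 3000.0,
    "Lingual gyrus": 4000.0,
    "Amygdala": 700.0,
    "Hippocampus": 1300.0,
    "Cerebellar hemisphere": 12000.0,
    "Insular cortex": 3500.0,
}


def default_region_means(atlas: RegionAtlas | None = None) -> np.ndarray:
    atlas = atlas or load_region_atlas()
    return np.array([DEFAULT_REGION_MEANS[r.name] for r in atlas.regions])


def default_workflow_biases(atlas: RegionAtlas | None = None) -> dict[str, np.ndarray]:
    """Per-region multiplicative bias vectors for the three workflows.

    BET runs 5% small everywhere; iBEAT runs 5% large on the
    skull-base-adjacent subset; the corrected workflow is unbiased.  The
    magnitudes are configurable placeholders — only the directions are
    anchored to the phenomenology being emulated.
    """
    atlas = atlas or load_region_atlas()
    ones = np.ones(64)
    ibeat = ones.copy()
    for i, r in enumerate(atlas.regions):
        if r.name in SKULL_BASE_REGIONS:
            ibeat[i] = 1.05
    return {"BET": ones * 0.95, "iBEAT": ibeat, "iBEAT_corrected": ones.copy()}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``region_mean_volumes`` / ``region_sd`` are per-region means and
    between-subject SDs on the volume scale (mm³); ``repeat_sd`` is the
    within-subject measurement SD added per repeated measurement.
    """

    n_subjects: int = 22
    seed: int = 0
    n_modules: int = 4
    within_module_corr: float = 0.6
    between_module_corr: float = 0.1
    region_mean_volumes: np.ndarray = field(default_factory=default_region_means)
    region_sd: np.ndarray | None = None
    workflow_bias: Mapping[str, np.ndarray] = field(
        default_factory=default_workflow_biases
    )
    repeat_sd: float = 1.0

    def __post_init__(self) -> None:
        self.region_mean_volumes = np.asarray(self.region_mean_volumes, dtype=float)
        if self.region_sd is None:
            self.region_sd = 0.1 * self.region_mean_volumes
        self.region_sd = np.asarray(self.region_sd, dtype=float)
        if self.region_mean_volumes.shape != (64,) or self.region_sd.shape != (64,):
            raise ValueError("region means and SDs must be 64-vectors")
        if np.any(self.region_mean_volumes <= 0) or np.any(self.region_sd <= 0):
            raise ValueError("region means and SDs must be positive")
        for wf, b in self.workflow_bias.items():
            b = np.asarray(b, dtype=float)
            if b.shape != (64,) or np.any(b <= 0):
                raise ValueError(f"bias vector for {wf!r} must be 64 positive reals")
        if self.repeat_sd < 0:
            raise ValueError("repeat_sd must be >= 0")
        if not (0 < self.within_module_corr < 1):
            raise ValueError("within_module_corr must lie in (0, 1)")
        if not (0 <= self.between_module_corr < 1):
            raise ValueError("between_module_corr must lie in [0, 1)")
        # fail fast on a non-positive-definite correlation target
        self.correlation_cholesky()

    def correlation_matrix(self) -> np.ndarray:
        return block_correlation_matrix(
            64, self.n_modules, self.within_module_corr, self.between_module_corr
        )

    def correlation_cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.correlation_matrix())
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "implied 64×64 correlation matrix is not positive definite"
            ) from exc


def block_correlation_matrix(
    n: int, n_modules: int, within: float, between: float
) -> np.ndarray:
    """Exchangeable block correlation: ``within`` inside equal-size modules,
    ``between`` across them, unit diagonal."""
    if n % n_modules:
        raise ValueError(f"{n} regions do not divide into {n_modules} equal modules")
    R = np.full((n, n), between, dtype=float)
    size = n // n_modules
    for m in range(n_modules):
        R[m * size : (m + 1) * size, m * size : (m + 1) * size] = within
    np.fill_diagonal(R, 1.0)
    return R


def module_assignments(n: int, n_modules: int) -> np.ndarray:
    """Module index of each region under the generator's block layout."""
    return np.repeat(np.arange(n_modules), n // n_modules)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # all sampling flows from the single cohort seed via fixed stage keys
    return np.random.default_rng(np.random.SeedSequence((seed, stage)))


_STAGE_LATENT, _STAGE_REPEAT, _STAGE_FIXTURE = 1, 2, 3


def _latent_volumes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw latent (bias-free, noise-free) volumes: shape (n_subjects, 64).

    Per region the marginal is log-normal with exactly the configured mean
    and SD on the volume scale; the block correlation acts on the latent
    Gaussian (log) scale.
    """
    L = config.correlation_cholesky()
    z = rng.standard_normal((config.n_subjects, 64)) @ L.T
    m, s = config.region_mean_volumes, config.region_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    return np.exp(mu + np.sqrt(sigma2) * z)


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i:03d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> dict[str, VolumeTable]:
    """Generate one volume table per workflow from a shared latent cohort.

    The latent subject draw is identical across workflows; the per-region
    multiplicative bias vectors are the only systematic difference, so any
    downstream workflow contrast reflects the biases alone.
    """
    rng = _stage_rng(config.seed, _STAGE_LATENT)
    latent = _latent_volumes(config, rng)
    atlas = load_region_atlas()
    tables = {}
    for wf, bias in config.workflow_bias.items():
        tables[wf] = VolumeTable(
            subject_ids=_subject_ids(config.n_subjects),
            region_names=atlas.column_names,
            values=latent * np.asarray(bias, dtype=float),
            workflow=wf,
        )
    return tables


def generate_repeats(config: CohortConfig, n_repeats: int = 2) -> list[VolumeTable]:
    """Repeated measurements of the unbiased workflow's latent volumes.

    All repeats share the latent subject volumes; each adds independent
    zero-mean Gaussian noise with SD ``repeat_sd`` (volume scale).  The
    tables carry ``measurement_id`` 1..n_repeats.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    latent = _latent_volumes(config, _stage_rng(config.seed, _STAGE_LATENT))
    noise_rng = _stage_rng(config.seed, _STAGE_REPEAT)
    atlas = load_region_atlas()
    tables = []
    for rep in range(1, n_repeats + 1):
        noise = noise_rng.standard_normal(latent.shape) * config.repeat_sd
        values = np.maximum(latent + noise, np.finfo(float).tiny)
        tables.append(
            VolumeTable(
                subject_ids=_subject_ids(config.n_subjects),
                region_names=atlas.column_names,
                values=values,
                workflow="iBEAT_corrected",
                measurement_id=rep,
            )
        )
    return tables


def generate_registration_fixture(
    seed: int,
    region_voxel_counts: Mapping[int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine_scale: float = 1.0,
    jacobian_field: str = "uniform",
    jacobian_value: float = 1.0,
    jacobian_amplitude: float = 0.05,
    smoothing_sigma: float = 2.0,
) -> RegistrationFixture:
    """Build a synthetic template label map + transforms + Jacobian field.

    Regions are laid out as disjoint runs of voxels in a box just large
    enough to hold them (overlap is impossible by construction).  The rigid
    transform is the identity rotation and the affine 3×3 block is
    ``affine_scale``·I.  ``jacobian_field`` is either ``"uniform"`` (constant
    ``jacobian_value``) or ``"smooth"`` (1 + Gaussian-smoothed noise of
    amplitude ``jacobian_amplitude``, strictly positive).
    """
    if affine_scale <= 0:
        raise ValueError("affine_scale must be positive")
    counts = {int(c): int(n) for c, n in region_voxel_counts.items()}
    if any(c <= 0 for c in counts) or any(n <= 0 for n in counts.values()):
        raise ValueError("label codes and voxel counts must be positive")
    total = sum(counts.values())
    side = int(np.ceil((total * 1.25) ** (1 / 3))) + 1
    shape = (side, side, side)
    flat = np.zeros(int(np.prod(shape)), dtype=np.int32)
    pos = 0
    for code in sorted(counts):
        flat[pos : pos + counts[code]] = code
        pos += counts[code]
    label_map = flat.reshape(shape)

    rng = np.random.default_rng(np.random.SeedSequence((seed, _STAGE_FIXTURE)))
    if jacobian_field == "uniform":
        if jacobian_value <= 0:
            raise ValueError("jacobian_value must be positive")
        jac = np.full(shape, float(jacobian_value))
    elif jacobian_field == "smooth":
        noise = rng.standard_normal(shape)
        noise = ndimage.gaussian_filter(noise, sigma=smoothing_sigma)
        peak = np.max(np.abs(noise))
        if peak > 0:
            noise = noise / peak * min(jacobian_amplitude, 0.99)
        jac = 1.0 + noise
    else:
        raise ValueError("jacobian_field must be 'uniform' or 'smooth'")

    affine = np.eye(4)
    affine[:3, :3] *= affine_scale
    return RegistrationFixture(
        label_map=label_map,
        voxel_size=voxel_size,
        rigid=np.eye(4),
        affine=affine,
        jacobian=jac,
    )
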