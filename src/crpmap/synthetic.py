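"""Synthetic cohort, imaging, expression and annotation generators.

Every input the analysis pipeline consumes can be generated here with known
planted ground truth: a clinical cohort with a latent mediation structure
(CRP -> brain -> behavior), BOLD-like 4D series whose low-frequency amplitude
in a planted voxel cluster tracks serum CRP, a skeletonized diffusion-metric
panel with a planted negative CRP slope, a region x gene expression matrix
with spatially autocorrelated gene maps and a planted enriched gene category,
and smooth region-level annotation maps (neurotransmitter- and behavioral-
term-like) with a planted spatial correlation to a phenotype pattern.

All generators are deterministic given their seed: the same seed reproduces
outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "GridSpec",
    "RegionAtlas",
    "generate_subject_table",
    "generate_bold",
    "iter_bold",
    "generate_skeleton_panel",
    "make_atlas",
    "generate_expression",
    "generate_annotation_maps",
]


class ConfigurationError(ValueError):
    """Raised when a generator spec is invalid; names the offending field."""


# Cohort demographics follow the published sample this generator emulates:
# 120 patients / 118 controls; CRP is right-skewed (SD > mean), modelled
# log-normal with (mu, sigma) matching mean 0.98 and SD 1.27 mg/L and clamped
# to the observed range 0.02-6.39 mg/L.
@dataclass
class CohortSpec:
    n_patients: int = 120
    n_controls: int = 118
    seed: int = 0
    crp_log_mean: float = -0.513
    crp_log_sd: float = 0.993
    crp_range: tuple[float, float] = (0.02, 6.39)
    age_mean: float = 42.89
    age_sd: float = 11.03
    female_prop: float = 81.0 / 120.0
    education_mean: float = 8.87
    education_sd: float = 3.66
    fd_mean: float = 0.13
    fd_sd: float = 0.09
    bmi_mean: float = 22.97
    bmi_sd: float = 3.80
    # Planted standardized effect sizes.  beta_crp_falff=None means the BOLD
    # cluster amplitude driver is the mediation latent M itself, so the
    # CRP-amplitude correlation equals path a and the extracted fALFF is a
    # valid mediator end to end.  Setting beta_crp_falff explicitly decouples
    # the imaging effect from the mediation structure.
    beta_crp_falff: float | None = None
    beta_crp_ad: float = -0.5
    a: float = 0.5
    b: float = 0.5
    c_prime: float = 0.0
    noise_y_sd: float = 1.0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        if self.n_controls < 4:
            raise ConfigurationError("n_controls must be >= 4")
        for name in ("crp_log_sd", "age_sd", "education_sd", "fd_sd", "bmi_sd",
                     "noise_y_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ConfigurationError("female_prop must be in [0, 1]")
        for name in ("a", "b"):
            if abs(getattr(self, name)) > 1:
                raise ConfigurationError(f"path {name} must be in [-1, 1]")
        if self.beta_crp_falff is not None and abs(self.beta_crp_falff) > 1:
            raise ConfigurationError("beta_crp_falff must be in [-1, 1]")
        if abs(self.beta_crp_ad) > 1:
            raise ConfigurationError("beta_crp_ad must be in [-1, 1]")


@dataclass
class GridSpec:
    """Voxel grid for BOLD generation; desk-scale by default.

    24^3 voxels at TR 2 s with 200 timepoints resolves the 0.01 Hz lower band
    edge (record length 400 s -> frequency resolution 0.0025 Hz).
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    tr: float = 2.0
    n_timepoints: int = 200
    mask: np.ndarray | None = None
    cluster_seed_voxels: np.ndarray | None = None  # (k, 3) int voxel indices

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        if self.cluster_seed_voxels is None:
            c = np.array(self.shape) // 2
            offs = np.stack(np.meshgrid(*[np.arange(-1, 2)] * 3,
                                        indexing="ij"), -1).reshape(-1, 3)
            self.cluster_seed_voxels = c[None, :] + offs
        self.cluster_seed_voxels = np.asarray(self.cluster_seed_voxels, int)

    def validate(self) -> None:
        if self.n_timepoints < 64:
            raise ConfigurationError("n_timepoints must be >= 64")
        if not self.mask.any():
            raise ConfigurationError("mask is empty")
        if self.mask.shape != tuple(self.shape):
            raise ConfigurationError("mask shape mismatch")
        if self.n_timepoints * self.tr < 1.0 / 0.01:
            raise ConfigurationError(
                "n_timepoints*tr too short to resolve 0.01 Hz")
        cv = self.cluster_seed_voxels
        if not self.mask[cv[:, 0], cv[:, 1], cv[:, 2]].all():
            raise ConfigurationError("cluster_seed_voxels must lie in mask")

    @property
    def cluster_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        cv = self.cluster_seed_voxels
        m[cv[:, 0], cv[:, 1], cv[:, 2]] = True
        return m


@dataclass
class RegionAtlas:
    """Volumetric parcellation: region labels 1..R, centroids in mm."""

    labels: np.ndarray                 # int volume, 0 = background
    centroids: np.ndarray              # (R, 3) mm
    gm_probability: np.ndarray         # (R,) in [0, 1]
    voxel_size: float = 3.0

    @property
    def n_regions(self) -> int:
        return self.centroids.shape[0]

    def validate(self) -> None:
        R = self.n_regions
        if R < 10:
            raise ConfigurationError("atlas needs >= 10 regions")
        present = np.unique(self.labels)
        if not np.isin(np.arange(1, R + 1), present).all():
            raise ConfigurationError("every region must be non-empty")
        if not np.isfinite(self.centroids).all():
            raise ConfigurationError("centroids must be finite")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _stage_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def generate_subject_table(spec: CohortSpec) -> pd.DataFrame:
    """Generate the per-subject phenotype/covariate table.

    Columns include the serum CRP concentration (mg/L), its standardized
    log value ``crp_z`` (the latent that drives every planted effect), the
    nuisance covariates, the mediation latent ``m_latent`` (later embedded
    in the imaging signal) and clinical scores built from the structural
    model Y = c'·X + b·M + covariate effects + noise.
    """
    spec.validate()
    rngs = _stage_seeds(spec.seed, 8)
    n = spec.n_patients + spec.n_controls
    group = np.array(["MDD"] * spec.n_patients + ["HC"] * spec.n_controls)

    crp_z = rngs[0].standard_normal(n)
    crp = np.exp(spec.crp_log_mean + spec.crp_log_sd * crp_z)
    crp = np.clip(crp, *spec.crp_range)

    age = np.clip(rngs[1].normal(spec.age_mean, spec.age_sd, n), 18, 65)
    sex = (rngs[2].random(n) < spec.female_prop).astype(int)  # 1 = female
    edu = np.clip(rngs[3].normal(spec.education_mean, spec.education_sd, n),
                  0, 20)
    fd = np.clip(rngs[4].normal(spec.fd_mean, spec.fd_sd, n), 0.02, 0.8)
    bmi = np.clip(rngs[5].normal(spec.bmi_mean, spec.bmi_sd, n), 14, 35)

    # Mediation structural model on standardized variables; paths apply to
    # patients, controls get pure noise (planted effects are patient-only).
    is_pat = group == "MDD"
    em = rngs[6].standard_normal(n)
    m = np.where(is_pat,
                 spec.a * crp_z + np.sqrt(max(1 - spec.a ** 2, 0.0)) * em,
                 em)
    ey = rngs[7].standard_normal(n)
    age_z = (age - age.mean()) / age.std()
    y = np.where(is_pat,
                 spec.c_prime * crp_z + spec.b * m,
                 0.0) - 0.1 * age_z + spec.noise_y_sd * ey

    df = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
        "group": group,
        "crp": crp,
        "crp_z": crp_z,
        "age": age,
        "sex": sex,
        "education": edu,
        "fd": fd,
        "bmi": bmi,
        "m_latent": m,
        "cpt_ip": y,
        # additional clinical columns sharing the same structural form
        "hamd": np.where(is_pat, 28.84, 1.13) + 5.0 * ey,
        "n2_percent": 64.78 + 6.0 * y,
        "n3_percent": 6.15 - 3.0 * y,
    })
    return df


def _amplitude_driver(spec: CohortSpec, subjects: pd.DataFrame,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-subject standardized driver of the planted cluster amplitude."""
    is_pat = (subjects["group"] == "MDD").to_numpy()
    if spec.beta_crp_falff is None:
        u = subjects["m_latent"].to_numpy().copy()
    else:
        beta = spec.beta_crp_falff
        eps = rng.standard_normal(len(subjects))
        u = beta * subjects["crp_z"].to_numpy() + \
            np.sqrt(max(1 - beta ** 2, 0.0)) * eps
    u = np.where(is_pat, u, rng.standard_normal(len(subjects)))
    return u


def iter_bold(spec: CohortSpec, grid: GridSpec, subjects: pd.DataFrame,
              amp_base: float = 1.5, amp_gain: float = 0.7,
              noise_sd: float = 0.25, f_signal: float = 0.05):
    """Yield (subject_id, 4D volume) one subject at a time.

    Each in-mask voxel's series is white Gaussian noise plus a low-frequency
    sinusoid (f_signal in the 0.01-0.1 Hz band, random phase per voxel).
    Inside the planted cluster the sinusoid amplitude is
    ``amp_base * exp(amp_gain * u_i)`` with u the subject's standardized
    amplitude driver (monotone and positive, so measured band amplitude and
    fALFF track the driver with little attenuation); elsewhere it is
    CRP-independent (amp_base).  Out-of-mask voxels are all-zero.
    """
    spec.validate()
    grid.validate()
    rngs = _stage_seeds(spec.seed + 1_000_003, 2)
    u = _amplitude_driver(spec, subjects, rngs[0])
    master = rngs[1]
    t = np.arange(grid.n_timepoints) * grid.tr
    cmask = grid.cluster_mask
    flat_mask = grid.mask.ravel()
    flat_cluster = cmask.ravel()[flat_mask]
    nvox = int(flat_mask.sum())
    sub_seeds = master.integers(0, 2 ** 31 - 1, size=len(subjects))
    for i, sid in enumerate(subjects["subject_id"]):
        r = np.random.default_rng(sub_seeds[i])
        amp = np.full(nvox, amp_base)
        amp[flat_cluster] = amp_base * np.exp(amp_gain * u[i])
        phase = r.uniform(0, 2 * np.pi, nvox)
        series = noise_sd * r.standard_normal((nvox, grid.n_timepoints))
        series += amp[:, None] * np.sin(
            2 * np.pi * f_signal * t[None, :] + phase[:, None])
        vol = np.zeros(grid.shape + (grid.n_timepoints,))
        vol.reshape(-1, grid.n_timepoints)[flat_mask] = series
        yield sid, vol


def generate_bold(spec: CohortSpec, grid: GridSpec,
                  subjects: pd.DataFrame, **kw) -> dict[str, np.ndarray]:
    """Materialize all subjects' 4D volumes (see :func:`iter_bold`)."""
    return {sid: vol for sid, vol in iter_bold(spec, grid, subjects, **kw)}


def generate_skeleton_panel(spec: CohortSpec, subjects: pd.DataFrame,
                            n_voxels: int = 300,
                            strip: tuple[int, int] = (120, 160),
                            base: float = 1.2, signal_sd: float = 0.05,
                            noise_sd: float = 0.01,
                            smooth_vox: float = 4.0):
    """Subjects x skeleton-voxel panel of an AD-like diffusion metric.

    The skeleton is a 1-D chain (adjacency i~i+1, a stand-in for a thinned
    white-matter skeleton).  Values are a smooth baseline profile plus
    spatially smooth subject noise; inside the planted contiguous strip a
    shared per-subject driver with correlation ``beta_crp_ad`` to
    standardized log-CRP is added (patients only; negative by default,
    mimicking reduced axial diffusivity at higher inflammation).

    Returns (panel (n, V), adjacency list of (i, j) edges, strip slice).
    """
    spec.validate()
    if not 0 <= strip[0] < strip[1] <= n_voxels:
        raise ConfigurationError("strip must be a sub-interval of the chain")
    rngs = _stage_seeds(spec.seed + 2_000_003, 3)
    n = len(subjects)
    is_pat = (subjects["group"] == "MDD").to_numpy()
    beta = spec.beta_crp_ad
    eps = rngs[0].standard_normal(n)
    driver = beta * subjects["crp_z"].to_numpy() + \
        np.sqrt(max(1 - beta ** 2, 0.0)) * eps
    driver = np.where(is_pat, driver, rngs[1].standard_normal(n))

    # smooth per-subject noise field along the chain
    white = rngs[2].standard_normal((n, n_voxels))
    x = np.arange(n_voxels)
    kern = np.exp(-0.5 * ((x - n_voxels // 2) / smooth_vox) ** 2)
    kern /= kern.sum()
    smooth = np.apply_along_axis(
        lambda v: np.convolve(v, kern, mode="same"), 1, white)
    smooth /= smooth.std(axis=1, keepdims=True).clip(1e-12)

    panel = base + noise_sd * smooth
    panel[:, strip[0]:strip[1]] += signal_sd * driver[:, None]
    edges = [(i, i + 1) for i in range(n_voxels - 1)]
    return panel, edges, slice(*strip)


def make_atlas(shape: tuple[int, int, int] = (24, 24, 24),
               n_regions: int = 60, voxel_size: float = 3.0,
               seed: int = 0) -> RegionAtlas:
    """Random Voronoi parcellation of the volume into contiguous regions."""
    if n_regions < 10:
        raise ConfigurationError("n_regions must be >= 10")
    rng = _rng(seed)
    shape = tuple(shape)
    seeds = rng.uniform(0, 1, (n_regions, 3)) * np.array(shape)
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), -1).reshape(-1, 3)
    d2 = ((ijk[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
    labels = (d2.argmin(1) + 1).reshape(shape)
    centroids = np.array([ijk[labels.ravel() == r + 1].mean(0)
                          for r in range(n_regions)]) * voxel_size
    gm = 0.3 + 0.6 / (1 + np.exp(-rng.standard_normal(n_regions)))
    atlas = RegionAtlas(labels=labels, centroids=centroids,
                        gm_probability=gm, voxel_size=voxel_size)
    atlas.validate()
    return atlas


def _grf(centroids: np.ndarray, n_fields: int, length_scale: float,
         rng: np.random.Generator) -> np.ndarray:
    """Gaussian random fields over region centroids, exponential covariance.

    Returns (n_fields, R), each field standardized to zero mean/unit sd.
    """
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    cov = np.exp(-d / length_scale)
    # jitter for numerical PSD
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(cov)))
    f = rng.standard_normal((n_fields, len(cov))) @ L.T
    f -= f.mean(1, keepdims=True)
    f /= f.std(1, keepdims=True).clip(1e-12)
    return f


def generate_expression(atlas: RegionAtlas, n_genes: int = 400,
                        n_categories: int = 24,
                        planted_category: str = "planted",
                        phenotype: np.ndarray | None = None,
                        planted_size: int = 15,
                        planted_noise_sd: float = 0.5,
                        length_scale: float = 30.0,
                        seed: int = 0):
    """Region x gene expression matrix with a planted enriched category.

    Each gene is a Gaussian random field over the atlas centroids with
    exponential spatial covariance (length scale in mm), so gene maps carry
    spatial autocorrelation like real regional expression.  Genes belonging
    to ``planted_category`` are noisy copies of the supplied phenotype
    pattern (``phenotype + planted_noise_sd * GRF``).

    Returns (expr DataFrame regions x genes, categories DataFrame with
    columns category_id/gene_id, phenotype used).
    """
    atlas.validate()
    if n_categories < 2:
        raise ConfigurationError("n_categories must be >= 2")
    rngs = _stage_seeds(seed + 3_000_003, 4)
    R = atlas.n_regions
    genes = _grf(atlas.centroids, n_genes, length_scale, rngs[0]).T  # R x G
    if phenotype is None:
        phenotype = _grf(atlas.centroids, 1, length_scale, rngs[1])[0]
    phenotype = np.asarray(phenotype, float)
    z = (phenotype - phenotype.mean()) / phenotype.std()

    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    planted_idx = rngs[2].choice(n_genes, size=planted_size, replace=False)
    noise = _grf(atlas.centroids, planted_size, length_scale, rngs[2])
    genes[:, planted_idx] = (z[:, None] + planted_noise_sd * noise.T)

    rows = []
    pool = np.setdiff1d(np.arange(n_genes), planted_idx)
    for c in range(n_categories - 1):
        size = int(rngs[3].integers(8, 31))
        members = rngs[3].choice(pool, size=size, replace=False)
        rows += [(f"cat{c + 1:03d}", gene_ids[g]) for g in members]
    rows += [(planted_category, gene_ids[g]) for g in planted_idx]
    categories = pd.DataFrame(rows, columns=["category_id", "gene_id"])

    expr = pd.DataFrame(genes, columns=gene_ids,
                        index=[f"R{r + 1:03d}" for r in range(R)])
    return expr, categories, phenotype


def generate_annotation_maps(atlas: RegionAtlas, k_maps: int = 27,
                             planted: dict[str, float] | None = None,
                             phenotype: np.ndarray | None = None,
                             length_scale: float = 30.0,
                             prefix: str = "map",
                             seed: int = 0) -> pd.DataFrame:
    """Smooth region-level annotation maps (neurotransmitter/behavior-like).

    ``planted`` maps name -> target correlation r with the phenotype pattern:
    those maps are built as r*z + sqrt(1-r^2)*GRF.  Remaining maps are
    independent GRFs.  Returns DataFrame region x map with a region_id index.
    """
    atlas.validate()
    rngs = _stage_seeds(seed + 4_000_003, 2)
    planted = planted or {}
    if phenotype is None and planted:
        raise ConfigurationError("phenotype required when planting maps")
    cols = {}
    base = _grf(atlas.centroids, k_maps + len(planted), length_scale, rngs[0])
    if phenotype is not None:
        z = (phenotype - phenotype.mean()) / phenotype.std()
    j = 0
    for name, r in planted.items():
        if abs(r) > 1:
            raise ConfigurationError(f"planted r for {name} must be in [-1,1]")
        cols[name] = r * z + np.sqrt(1 - r ** 2) * base[j]
        j += 1
    for k in range(k_maps - len(planted)):
        cols[f"{prefix}_{k + 1:02d}"] = base[j]
        j += 1
    df = pd.DataFrame(cols, index=[f"R{r + 1:03d}"
                                   for r in range(atlas.n_regions)])
    df.index.name = "region_id"
    return df
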