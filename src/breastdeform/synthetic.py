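"""Synthetic study data: breast MR phantoms and elastography cohorts.

Two generators make every downstream stage testable without patient data:

* :func:`generate_phantom` builds a prone T1-weighted-like volume — a
  hemiellipsoidal breast attached to a posterior chest slab, with a
  central retroareolar fibroglandular (FGT) core sized to a requested
  percent density, a smooth multiplicative bias field, and additive
  Gaussian noise — returning the ground-truth masks and nipple location.

* :func:`sample_cohort` draws a cohort of subjects whose age, breast
  volume, whole and local percent density, and shear-wave stiffness
  follow a multivariate normal with configurable means, SDs and pairwise
  correlations, plus 3-5 stiffness repeats per subject whose spread is
  controlled by a gamma-distributed per-subject coefficient of variation.

Defaults reproduce a 20-subject shear-wave elastography study of normal
breasts: stiffness 2.3 +/- 0.8 m/s, breast volume 584.4 +/- 170.4 cm^3,
FGT volume 72.7 +/- 31.3 cm^3, whole-breast density 13.1 +/- 5.8 %, ROI
depth 1.41 +/- 0.38 cm, mean repeat CV 12.7 %, and the published
correlations r(age, density) = -0.56, r(age, stiffness) = 0.29,
r(volume, stiffness) = -0.14, r(density, stiffness) = -0.09,
r(local density, stiffness) = -0.12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortConfig",
    "generate_phantom",
    "sample_cohort",
    "nearest_psd",
]

LATENT_VARS = (
    "age",
    "breast_volume",
    "whole_percent_density",
    "local_percent_density",
    "stiffness",
)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, contrast and artifact parameters of a breast phantom.

    The breast is a hemiellipsoid with semiaxes ``breast_semiaxes_mm``
    (lateral x, anterior y, superior z) seated on a chest slab of
    thickness ``chest_slab_mm``; anterior is +y, so prone gravity acts
    along +y (away from the chest) and supine gravity along -y.
    """

    grid_shape: tuple = (72, 56, 72)
    voxel_size_mm: float = 2.0
    breast_semiaxes_mm: tuple = (60.0, 70.0, 60.0)
    chest_slab_mm: float = 20.0
    target_percent_density: float = 13.1
    fat_intensity: float = 400.0
    fgt_intensity: float = 150.0
    chest_intensity: float = 180.0
    bias_amplitude: float = 0.2
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.breast_semiaxes_mm):
            raise ValueError("breast semiaxes must be positive")
        if not 0.0 <= self.target_percent_density <= 100.0:
            raise ValueError("target_percent_density must be in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")


@dataclass
class Phantom:
    """A generated phantom with its ground truth."""

    image: ImageVolume
    breast_mask: np.ndarray
    fgt_mask: np.ndarray
    chest_mask: np.ndarray
    nipple_location_mm: np.ndarray  # world coordinates
    chest_plane_y_mm: float  # posterior fixation plane (breast base)


def _fgt_voxels(breast: np.ndarray, xyz: np.ndarray, center: np.ndarray,
                semiaxes: np.ndarray, t: float) -> np.ndarray:
    """FGT mask at core scale ``t``: concentric ellipsoid clipped to the breast."""
    if t <= 0:
        return np.zeros_like(breast)
    q = ((xyz - center) / (t * semiaxes)) ** 2
    return breast & (q.sum(axis=-1) <= 1.0)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build a prone breast phantom with known tissue ground truth.

    The FGT core is an ellipsoid centred retroareolarly (a quarter of the
    anterior semiaxis in front of the chest wall); its scale is found by
    bisection so the FGT voxel fraction is within one percentage point of
    ``target_percent_density``. Raises ``ValueError`` naming the
    achievable range when the target exceeds what the geometry allows.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    # voxel centers at (i + 1/2) h: keeps flat interfaces (the chest plane)
    # off the sampling lattice, so voxel counting stays volume-unbiased
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = spec.voxel_size_mm / 2.0
    vol = ImageVolume(np.zeros(shape, dtype=np.float64), affine)

    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    xyz = vol.index_to_world(idx)  # voxel centers, mm
    extent = np.array(shape) * spec.voxel_size_mm

    a, b, c = spec.breast_semiaxes_mm
    y0 = spec.chest_slab_mm
    center = np.array([extent[0] / 2.0, y0, extent[2] / 2.0])
    semiaxes = np.array([a, b, c])

    q = ((xyz - center) / semiaxes) ** 2
    breast = (q.sum(axis=-1) <= 1.0) & (xyz[..., 1] >= y0)
    chest = xyz[..., 1] < y0
    if not breast.any():
        raise ValueError("breast geometry does not fit inside the grid")

    n_breast = int(breast.sum())
    target = spec.target_percent_density / 100.0
    fgt_center = center + np.array([0.0, 0.25 * b, 0.0])

    if target == 0:
        fgt = np.zeros_like(breast)
    else:
        # the FGT core may grow to at most 0.85x the breast semiaxes: a
        # subcutaneous fat rim always remains, as in real anatomy
        t_max = 0.85
        frac_max = _fgt_voxels(breast, xyz, fgt_center, semiaxes, t_max).sum() / n_breast
        if target > frac_max + 0.01:
            raise ValueError(
                "target_percent_density "
                f"{spec.target_percent_density:.1f}% unreachable; achievable "
                f"range is 0-{100 * frac_max:.1f}% for this geometry"
            )
        lo, hi = 0.0, t_max
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            frac = _fgt_voxels(breast, xyz, fgt_center, semiaxes, mid).sum() / n_breast
            if abs(frac - target) < 0.005:
                break
            if frac < target:
                lo = mid
            else:
                hi = mid
        fgt = _fgt_voxels(breast, xyz, fgt_center, semiaxes, mid)
        frac = fgt.sum() / n_breast
        if abs(frac - target) > 0.01:
            raise ValueError(
                f"could not match target density {spec.target_percent_density:.1f}% "
                f"(best achievable near {100 * frac:.1f}%) on this voxel grid"
            )

    data = np.zeros(shape)
    data[breast] = spec.fat_intensity
    data[fgt] = spec.fgt_intensity
    data[chest] = spec.chest_intensity

    if spec.bias_amplitude > 0:
        u = 2.0 * xyz / extent - 1.0  # normalized [-1, 1] coords
        coef = rng.standard_normal(10)
        ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
        poly = (coef[0] + coef[1] * ux + coef[2] * uy + coef[3] * uz
                + coef[4] * ux * uy + coef[5] * ux * uz + coef[6] * uy * uz
                + coef[7] * ux ** 2 + coef[8] * uy ** 2 + coef[9] * uz ** 2)
        poly = poly - poly.mean()
        peak = np.abs(poly).max()
        if peak > 0:
            data = data * (1.0 + spec.bias_amplitude * poly / peak)

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)

    # nipple: anterior-most breast-surface voxel on the mid-sagittal slice
    ix = int(round(vol.world_to_index(center)[0]))
    slice_mask = breast[ix]
    jj, kk = np.nonzero(slice_mask)
    j_star = jj.max()
    k_star = int(np.round(kk[jj == j_star].mean()))
    nipple = vol.index_to_world([ix, int(j_star), k_star])

    return Phantom(
        image=vol.like(data),
        breast_mask=breast,
        fgt_mask=fgt,
        chest_mask=chest,
        nipple_location_mm=np.asarray(nipple, float),
        chest_plane_y_mm=float(y0),
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def nearest_psd(matrix: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix onto the PSD cone.

    Eigenvalues are clipped at a small positive floor and the result is
    rescaled back to a unit diagonal. A matrix that is already PSD is
    returned unchanged (up to floating point).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    if w.min() >= floor:
        return m.copy()
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CohortConfig:
    """Moments and correlation structure of the synthetic cohort.

    ``correlations`` maps unordered variable pairs (names from
    :data:`LATENT_VARS`) to latent Pearson coefficients; missing pairs
    default to 0 except volume-density, which — unless supplied — is
    derived in closed form so that the implied mean FGT volume
    E[d*v]/100 = (mu_d mu_v + r sigma_d sigma_v)/100 equals
    ``fgt_volume_mean`` (percent density times breast volume must
    average to the configured FGT volume).
    """

    n_subjects: int = 20
    age_mean: float = 51.7
    age_sd: float = 13.5
    breast_volume_mean: float = 584.4
    breast_volume_sd: float = 170.4
    fgt_volume_mean: float = 72.7
    fgt_volume_sd: float = 31.3
    whole_density_mean: float = 13.1
    whole_density_sd: float = 5.8
    local_density_mean: float = 30.0
    local_density_sd: float = 15.0
    stiffness_mean: float = 2.3
    stiffness_sd: float = 0.8
    roi_depth_mean: float = 1.41
    roi_depth_sd: float = 0.38
    roi_window_cm: tuple = (1.0, 0.5)
    mean_cv: float = 12.7
    cv_gamma_shape: float = 2.0
    n_repeats_range: tuple = (3, 5)
    repeat_count_probs: tuple = (0.7, 0.15, 0.15)
    stiffness_floor: float = 0.1
    correlations: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        for name in ("age_sd", "breast_volume_sd", "fgt_volume_sd",
                     "whole_density_sd", "local_density_sd", "stiffness_sd",
                     "roi_depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mean_cv < 0:
            raise ValueError("mean_cv must be nonnegative")
        lo, hi = self.n_repeats_range
        if not (2 <= lo <= hi):
            raise ValueError("n_repeats_range must satisfy 2 <= lo <= hi")
        if len(self.repeat_count_probs) != hi - lo + 1:
            raise ValueError("repeat_count_probs length must match n_repeats_range")

    def _default_volume_density_r(self) -> float:
        denom = self.whole_density_sd * self.breast_volume_sd
        if denom == 0:
            return 0.0
        r = (100.0 * self.fgt_volume_mean
             - self.whole_density_mean * self.breast_volume_mean) / denom
        return float(np.clip(r, -0.99, 0.99))

    def correlation_matrix(self) -> np.ndarray:
        """The 5x5 latent matrix over :data:`LATENT_VARS`, PSD-projected."""
        defaults = {
            ("age", "whole_percent_density"): -0.56,
            ("age", "stiffness"): 0.29,
            ("breast_volume", "stiffness"): -0.14,
            ("whole_percent_density", "stiffness"): -0.09,
            ("local_percent_density", "stiffness"): -0.12,
            ("age", "breast_volume"): 0.0,
            ("breast_volume", "whole_percent_density"): self._default_volume_density_r(),
            ("whole_percent_density", "local_percent_density"): 0.5,
        }
        # complete the remaining pairs through whole density (product rule)
        defaults[("age", "local_percent_density")] = (
            defaults[("age", "whole_percent_density")]
            * defaults[("whole_percent_density", "local_percent_density")]
        )
        defaults[("breast_volume", "local_percent_density")] = (
            defaults[("breast_volume", "whole_percent_density")]
            * defaults[("whole_percent_density", "local_percent_density")]
        )
        for key, val in self.correlations.items():
            pair = tuple(key)
            if pair[0] not in LATENT_VARS or pair[1] not in LATENT_VARS:
                raise ValueError(f"unknown variable pair {pair}")
            defaults[pair] = float(val)
            defaults[(pair[1], pair[0])] = float(val)
        R = np.eye(len(LATENT_VARS))
        for i, vi in enumerate(LATENT_VARS):
            for j, vj in enumerate(LATENT_VARS):
                if i < j:
                    r = defaults.get((vi, vj), defaults.get((vj, vi), 0.0))
                    if not -1.0 <= r <= 1.0:
                        raise ValueError(f"correlation for {(vi, vj)} outside [-1, 1]")
                    R[i, j] = R[j, i] = r
        R = nearest_psd(R)
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix could not be projected to PSD")
        return R


def sample_cohort(config: CohortConfig | None = None,
                  n_subjects: int | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic elastography cohort as a tidy table.

    Latents (age, breast volume, whole and local percent density,
    reported stiffness) come from a single multivariate normal; FGT
    volume is derived as density x volume / 100 so the record is
    internally consistent. Per subject, 3-5 stiffness repeats are built
    around the reported value: each unreported repeat is the reported
    speed perturbed by multiplicative noise whose SD realises a
    gamma-distributed per-subject CV (corrected for small-sample bias of
    the sample SD); the reported repeat is the one whose simulated
    dense-tissue appearance score — tied to local density, independent
    of the measurement noise — is maximal.
    """
    config = config or CohortConfig()
    if n_subjects is not None or seed is not None:
        from dataclasses import replace
        kwargs = {}
        if n_subjects is not None:
            kwargs["n_subjects"] = n_subjects
        if seed is not None:
            kwargs["seed"] = seed
        config = replace(config, **kwargs)

    n = config.n_subjects
    rng = np.random.default_rng(config.seed)
    R = config.correlation_matrix()
    means = np.array([config.age_mean, config.breast_volume_mean,
                      config.whole_density_mean, config.local_density_mean,
                      config.stiffness_mean])
    sds = np.array([config.age_sd, config.breast_volume_sd,
                    config.whole_density_sd, config.local_density_sd,
                    config.stiffness_sd])

    z = rng.multivariate_normal(np.zeros(5), R, size=n, method="cholesky") if n else np.empty((0, 5))
    lat = means + sds * z
    age = lat[:, 0]
    volume = np.maximum(lat[:, 1], 1.0)
    whole_d = np.clip(lat[:, 2], 0.0, 100.0)
    local_d = np.clip(lat[:, 3], 0.0, 100.0)
    stiff = np.maximum(lat[:, 4], config.stiffness_floor)
    fgt = whole_d * volume / 100.0

    depth = np.maximum(rng.normal(config.roi_depth_mean, config.roi_depth_sd, size=n), 0.05)

    lo, hi = config.n_repeats_range
    ks = rng.choice(np.arange(lo, hi + 1), size=n, p=config.repeat_count_probs) if n else np.array([], int)
    subj_cv = rng.gamma(config.cv_gamma_shape,
                        (config.mean_cv / 100.0) / config.cv_gamma_shape, size=n)

    rows = []
    window = f"{config.roi_window_cm[0]:.2f}x{config.roi_window_cm[1]:.2f}"
    for i in range(n):
        k = int(ks[i])
        # sample-SD bias corrections: 1 + 1/(4k) for the SD estimator and
        # 1/sqrt(1 - 1/k) because the reported repeat carries no noise
        sigma = subj_cv[i] * (1.0 + 1.0 / (4 * k)) / np.sqrt(1.0 - 1.0 / k)
        eps = rng.normal(0.0, sigma, size=k)
        score = local_d[i] * (1.0 + rng.normal(0.0, 0.1, size=k))
        j_star = int(np.argmax(score))
        eps[j_star] = 0.0
        repeats = np.maximum(stiff[i] * (1.0 + eps), 0.05)
        rows.append({
            "subject_id": f"S{i + 1:04d}",
            "age": age[i],
            "breast_volume": volume[i],
            "fgt_volume": fgt[i],
            "whole_percent_density": whole_d[i],
            "local_percent_density": local_d[i],
            "stiffness": repeats[j_star],
            "stiffness_repeats": ";".join(f"{v:.6g}" for v in repeats),
            "roi_depth": depth[i],
            "roi_window": window,
        })
    columns = ["subject_id", "age", "breast_volume", "fgt_volume",
               "whole_percent_density", "local_percent_density", "stiffness",
               "stiffness_repeats", "roi_depth", "roi_window"]
    return pd.DataFrame(rows, columns=columns)
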