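"""Synthetic 4DCT breathing phantoms with analytic ground truth.

The generator stands in for clinical 4DCT pairs: it builds an ellipsoidal
lung of parenchyma-like density (~0.2, i.e. about -800 HU) inside a larger
soft-tissue body, deforms it with an analytic breathing transform (affine or
separable polynomial, optionally attenuated inside a spherical ventilation
defect), and constructs the inhale phase on its own grid so that tissue mass
is conserved exactly: rho_in(T(x)) = rho_ex(x) / J*(x).  Because the
transform, its Jacobian determinant J*, and the exhale density texture are
all closed-form functions of world position, the inhale image is evaluated
analytically (no resampling error) and the phantom carries exact per-voxel
truth grids for every quantity the imaging methods estimate.

A perfusion anomaly injects mass between the phases inside a sphere:
rho_in(T(x)) = (rho_ex(x) + m(x)) / J*(x), so the per-voxel mass change
J * rho_in(T(x)) - rho_ex(x) equals the implanted m(x) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    HU_MAX,
    HU_MIN,
    DisplacementField,
    HUImage,
    LungMask,
)

LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")

__all__ = [
    "AffineTransform",
    "PolynomialTransform",
    "DefectSpec",
    "PerfusionSpec",
    "PhantomTruth",
    "Phantom",
    "DoseGrid",
    "ReaderScore",
    "make_phantom",
    "make_dose",
    "simulate_reader",
    "scores_to_frame",
    "scores_from_frame",
    "LOBES",
]


# ---------------------------------------------------------------------------
# analytic breathing transforms


@dataclass
class AffineTransform:
    """x -> center + A (x - center) + translation, with constant gradient A."""

    matrix: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def apply(self, x: np.ndarray) -> np.ndarray:
        d = np.asarray(x, dtype=float) - self.center
        return self.center + d @ self.matrix.T + self.translation

    def gradient(self, x: np.ndarray) -> np.ndarray:
        shp = np.asarray(x).shape[:-1]
        return np.broadcast_to(self.matrix, shp + (3, 3)).copy()


@dataclass
class PolynomialTransform:
    """Separable per-axis polynomial map y_a = center_a + p_a(x_a - center_a).

    ``coeffs[a]`` are the polynomial coefficients (c1, c2, ...) of
    p_a(t) = c1 t + c2 t^2 + ... — no constant term, so the map has a
    diagonal gradient diag(p_a'(t)) and Jacobian determinant prod_a p_a'.
    """

    coeffs: Sequence[Sequence[float]]
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.coeffs = [np.asarray(c, dtype=float).ravel() for c in self.coeffs]
        if len(self.coeffs) != 3:
            raise ValueError("need one coefficient vector per axis")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        for a in range(3):
            t = x[..., a] - self.center[a]
            p = np.zeros_like(t)
            for k, c in enumerate(self.coeffs[a], start=1):
                p += c * t**k
            out[..., a] = self.center[a] + p
        return out

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.zeros(x.shape[:-1] + (3, 3))
        for a in range(3):
            t = x[..., a] - self.center[a]
            dp = np.zeros_like(t)
            for k, c in enumerate(self.coeffs[a], start=1):
                dp += k * c * t ** (k - 1)
            g[..., a, a] = dp
        return g


@dataclass
class DefectSpec:
    """Spherical ventilation defect: local expansion attenuated toward 1.

    The displacement is scaled by 1 - attenuation * b(r) with b = 1 inside
    the core (r <= core_fraction * radius), falling to 0 through a C^1
    cosine shell at r = radius.  With attenuation = 1 the core does not move
    at all (J = 1 exactly); the shell absorbs the displacement mismatch and
    slightly over-expands, as tissue around a non-ventilating region must.
    ``mask`` marks the core — the implanted defect proper.
    """

    center: np.ndarray
    radius_mm: float
    attenuation: float = 1.0
    core_fraction: float = 0.5

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius_mm <= 0:
            raise ValueError("defect radius must be > 0")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if not 0.0 < self.core_fraction < 1.0:
            raise ValueError("core_fraction must lie in (0, 1)")

    @property
    def _core_r(self) -> float:
        return self.core_fraction * self.radius_mm

    @property
    def _shell_w(self) -> float:
        return self.radius_mm - self._core_r

    def _bump(self, r: np.ndarray) -> np.ndarray:
        t = (r - self._core_r) / self._shell_w
        shell = 0.5 * (1 + np.cos(np.pi * np.clip(t, 0.0, 1.0)))
        return np.where(r <= self._core_r, 1.0, np.where(r < self.radius_mm, shell, 0.0))

    def weight(self, x: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(x, dtype=float) - self.center, axis=-1)
        return 1.0 - self.attenuation * self._bump(r)

    def weight_gradient(self, x: np.ndarray) -> np.ndarray:
        d = np.asarray(x, dtype=float) - self.center
        r = np.linalg.norm(d, axis=-1)
        safe_r = np.where(r > 1e-12, r, 1.0)
        in_shell = (r > self._core_r) & (r < self.radius_mm)
        t = (r - self._core_r) / self._shell_w
        db = np.where(
            in_shell,
            -0.5 * np.pi / self._shell_w * np.sin(np.pi * np.clip(t, 0.0, 1.0)),
            0.0,
        )
        return (-self.attenuation * db / safe_r)[..., None] * d

    def mask(self, x: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(x, dtype=float) - self.center, axis=-1)
        return r <= self._core_r


@dataclass
class PerfusionSpec:
    """Spherical mass-change implant of amplitude ``delta`` (density units)."""

    center: np.ndarray
    radius_mm: float
    delta: float = 0.05

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius_mm <= 0:
            raise ValueError("implant radius must be > 0")

    def mass_change(self, x: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(x, dtype=float) - self.center, axis=-1)
        return np.where(r <= self.radius_mm, self.delta, 0.0)

    def mask(self, x: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(x, dtype=float) - self.center, axis=-1)
        return r <= self.radius_mm


class _DeformationModel:
    """Full analytic map T(x) = x + w(x) (f(x) - x) with exact gradient."""

    def __init__(self, base, defect: Optional[DefectSpec]):
        self.base = base
        self.defect = defect

    def displacement(self, x: np.ndarray) -> np.ndarray:
        du = self.base.apply(x) - np.asarray(x, dtype=float)
        if self.defect is not None:
            du = du * self.defect.weight(x)[..., None]
        return du

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) + self.displacement(x)

    def jacobian_matrix(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        gf = self.base.gradient(x)  # (..., 3, 3)
        eye = np.eye(3)
        if self.defect is None:
            return eye + (gf - eye)
        w = self.defect.weight(x)[..., None, None]
        gw = self.defect.weight_gradient(x)  # (..., 3)
        du = self.base.apply(x) - x  # (..., 3)
        outer = du[..., :, None] * gw[..., None, :]
        return eye + w * (gf - eye) + outer

    def jacobian_det(self, x: np.ndarray) -> np.ndarray:
        return np.linalg.det(self.jacobian_matrix(x))

    def inverse(self, y: np.ndarray, n_iter: int = 80, tol: float = 1e-10) -> np.ndarray:
        """Fixed-point inverse x = y - u(x); converges for sub-unit strain."""
        y = np.asarray(y, dtype=float)
        x = y.copy()
        for _ in range(n_iter):
            x_new = y - self.displacement(x)
            delta = np.max(np.abs(x_new - x))
            x = x_new
            if delta < tol:
                break
        return x


# ---------------------------------------------------------------------------
# phantom assembly


@dataclass
class PhantomTruth:
    """Exact per-voxel ground truth on the exhale grid."""

    jacobian: np.ndarray
    sv_air: np.ndarray  # analytic specific air-volume change (HU-method target)
    defect_mask: np.ndarray
    mass_change: np.ndarray
    seed: int

    def __post_init__(self):
        if np.any(self.jacobian <= 0):
            raise ValueError("truth Jacobian must be > 0 everywhere")


@dataclass
class Phantom:
    exhale: HUImage
    inhale: HUImage
    field: DisplacementField
    mask: LungMask
    mask_in: LungMask
    truth: PhantomTruth
    rho_ex: np.ndarray  # noise-free exhale density grid
    rho_in: np.ndarray  # noise-free inhale density grid (inhale grid)


@dataclass
class DoseGrid:
    """Absorbed-dose grid (Gy) on the exhale grid."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("DoseGrid requires a 3-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose must be finite and >= 0")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.values.shape


def _world_grid(shape, spacing, origin):
    ax = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)


class _Anatomy:
    """Closed-form exhale scene: lung + body ellipsoids with smooth texture."""

    def __init__(self, center, lung_semi, body_semi, lung_density=0.2, texture_amp=0.15):
        self.center = np.asarray(center, dtype=float)
        self.lung_semi = np.asarray(lung_semi, dtype=float)
        self.body_semi = np.asarray(body_semi, dtype=float)
        self.lung_density = lung_density
        self.texture_amp = texture_amp

    def _ellipsoid(self, x, semi):
        d = (np.asarray(x, dtype=float) - self.center) / semi
        return np.sum(d * d, axis=-1) <= 1.0

    def lung(self, x):
        return self._ellipsoid(x, self.lung_semi)

    def body(self, x):
        return self._ellipsoid(x, self.body_semi)

    def density(self, x):
        """Smooth parenchyma-like texture inside the body, air outside.

        The texture is continuous across the whole body so that the lung
        boundary introduces no density discontinuity into the resampling
        paths the imaging methods exercise.
        """
        x = np.asarray(x, dtype=float)
        d = x - self.center
        k = 2 * np.pi / (2.5 * self.body_semi)
        tex = (
            np.sin(k[0] * d[..., 0])
            * np.sin(k[1] * d[..., 1] + 0.7)
            * np.sin(k[2] * d[..., 2] + 1.3)
        )
        rho = self.lung_density * (1.0 + self.texture_amp * tex)
        return np.where(self.body(x), rho, 0.0)


def make_phantom(
    shape=(48, 48, 48),
    spacing=(2.0, 2.0, 2.0),
    transform=None,
    defect: Optional[DefectSpec] = None,
    perfusion: Optional[PerfusionSpec] = None,
    noise_sd_hu: float = 20.0,
    seed: int = 0,
    lung_fraction: float = 0.32,
) -> Phantom:
    """Build a mass-consistent inhale/exhale phantom pair with exact truth.

    Parameters
    ----------
    shape, spacing
        Grid size (>= 32 per axis) and voxel size in mm; the inhale phase is
        generated on the same grid.
    transform
        :class:`AffineTransform` or :class:`PolynomialTransform` describing
        exhale -> inhale motion (default: isotropic 5%-per-axis expansion,
        J ~ 1.16, a typical tidal-breathing volume change).
    defect, perfusion
        Optional ventilation defect (local attenuation of the motion) and
        mass-change implant.
    noise_sd_hu
        Gaussian HU noise added to both phases after the mass-consistent
        construction (default 20 HU, typical 4DCT reconstruction noise).
    lung_fraction
        Lung ellipsoid semi-axes as a fraction of the grid extent.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("phantom grid must be at least 32 voxels per axis")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.zeros(3)
    extent = spacing * (np.array(shape) - 1)
    center = origin + extent / 2

    if transform is None:
        transform = AffineTransform(np.eye(3) * 1.05, center=center)
    if isinstance(transform, AffineTransform) and np.allclose(transform.center, 0):
        transform = AffineTransform(transform.matrix, transform.translation, center)

    anatomy = _Anatomy(center, lung_semi=lung_fraction * extent, body_semi=0.45 * extent)
    model = _DeformationModel(transform, defect)

    X = _world_grid(shape, spacing, origin)
    mask_ex = anatomy.lung(X)
    if not mask_ex.any():
        raise ValueError("empty lung mask; enlarge the grid or lung_fraction")

    J = model.jacobian_det(X)
    if np.any(J[mask_ex] <= 0):
        raise ValueError("transform folds (J* <= 0) inside the lung mask")

    rho_ex = anatomy.density(X)
    m = perfusion.mass_change(X) if perfusion is not None else np.zeros(shape)
    # density the deformed tissue presents at inhale, at the mapped point T(x)
    rho_in_at_T = (rho_ex + m) / J

    # inhale phase on its own grid via the exact inverse map
    Xback = model.inverse(X)
    J_back = model.jacobian_det(Xback)
    m_back = perfusion.mass_change(Xback) if perfusion is not None else 0.0
    rho_in = np.where(
        anatomy.body(Xback), (anatomy.density(Xback) + m_back) / J_back, 0.0
    )
    mask_in = anatomy.lung(Xback)

    rng = np.random.default_rng(seed)
    hu_ex = 1000.0 * rho_ex - 1000.0
    hu_in = 1000.0 * rho_in - 1000.0
    if noise_sd_hu > 0:
        hu_ex = hu_ex + rng.normal(0.0, noise_sd_hu, shape)
        hu_in = hu_in + rng.normal(0.0, noise_sd_hu, shape)
    hu_ex = np.clip(hu_ex, HU_MIN, HU_MAX)
    hu_in = np.clip(hu_in, HU_MIN, HU_MAX)

    u = model.displacement(X)

    with np.errstate(divide="ignore", invalid="ignore"):
        sv_air = (rho_ex - rho_in_at_T) / (rho_in_at_T * (1.0 - rho_ex))
    sv_air = np.where(mask_ex, sv_air, np.nan)

    truth = PhantomTruth(
        jacobian=J,
        sv_air=sv_air,
        defect_mask=(defect.mask(X) & mask_ex) if defect is not None else np.zeros(shape, bool),
        mass_change=np.where(mask_ex, m, 0.0),
        seed=seed,
    )
    return Phantom(
        exhale=HUImage(hu_ex, spacing.copy(), origin.copy()),
        inhale=HUImage(hu_in, spacing.copy(), origin.copy()),
        field=DisplacementField(u, spacing.copy(), origin.copy()),
        mask=LungMask(mask_ex, spacing.copy(), origin.copy()),
        mask_in=LungMask(mask_in, spacing.copy(), origin.copy()),
        truth=truth,
        rho_ex=rho_ex,
        rho_in=rho_in,
    )


def make_dose(
    shape,
    spacing=(2.0, 2.0, 2.0),
    origin=(0.0, 0.0, 0.0),
    target_center=None,
    target_radius_mm: float = 15.0,
    prescription_gy: float = 60.0,
    falloff_mm: Optional[float] = 20.0,
) -> DoseGrid:
    """Conformal synthetic dose: prescription inside a spherical target,
    Gaussian radial falloff outside; ``falloff_mm=None`` gives a uniform bath.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0")
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    extent = spacing * (np.array(shape) - 1)
    if target_center is None:
        target_center = origin + extent / 2
    target_center = np.asarray(target_center, dtype=float)
    if np.any(target_center < origin) or np.any(target_center > origin + extent):
        raise ValueError("dose target center lies outside the grid")
    if falloff_mm is None:
        return DoseGrid(np.full(shape, prescription_gy), spacing, origin)
    X = _world_grid(shape, spacing, origin)
    r = np.linalg.norm(X - target_center, axis=-1)
    d = np.clip(r - target_radius_mm, 0.0, None)
    dose = prescription_gy * np.exp(-0.5 * (d / falloff_mm) ** 2)
    return DoseGrid(dose, spacing, origin)


@dataclass
class ReaderScore:
    """One simulated radiologist call: defect present yes/no plus lobe."""

    patient: str
    method: str
    call: bool
    location: str = "none"

    def __post_init__(self):
        if self.location not in LOBES + ("none",):
            raise ValueError(f"unknown lobe label {self.location!r}")
        if (self.location == "none") != (not self.call):
            raise ValueError("location must be 'none' iff the call is negative")


def simulate_reader(
    truths,
    sensitivity: float = 0.9,
    specificity: float = 0.9,
    location_error_rate: float = 0.1,
    seed: int = 0,
    method: str = "reader",
):
    """Simulate binary defect calls against known truth bits.

    ``truths`` is a sequence of ``(patient_id, has_defect, true_lobe)``
    (``true_lobe`` ignored for negatives).  True positives are called with
    probability ``sensitivity``, true negatives with ``specificity``;
    positive calls carry the true lobe with probability
    ``1 - location_error_rate`` and a random other lobe otherwise.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("location_error_rate", location_error_rate),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = []
    for patient, has_defect, true_lobe in truths:
        if has_defect:
            call = bool(rng.random() < sensitivity)
        else:
            call = not bool(rng.random() < specificity)
        if call:
            if has_defect and rng.random() >= location_error_rate:
                loc = true_lobe
            else:
                others = [l for l in LOBES if not (has_defect and l == true_lobe)]
                loc = others[rng.integers(len(others))]
        else:
            loc = "none"
        scores.append(ReaderScore(str(patient), method, call, loc))
    return scores


def scores_to_frame(scores):
    """Reader scores as a DataFrame (patient, method, call, location)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"patient": s.patient, "method": s.method,
             "call": int(s.call), "location": s.location}
            for s in scores
        ]
    )


def scores_from_frame(frame):
    """Inverse of :func:`scores_to_frame`."""
    return [
        ReaderScore(str(r.patient), str(r.method), bool(r.call), str(r.location))
        for r in frame.itertuples()
    ]
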