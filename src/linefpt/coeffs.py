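"""Movement parameters → PDE coefficient fields.

A 2-D uncorrelated walk with exponential step lengths of mean ``alpha`` and
fix interval ``tau`` has E[L²] = 2·alpha², hence an isotropic diffusion
coefficient D = E[L²]/(4·tau) = alpha²/(2·tau).

On a line with axial von Mises headings (concentration kappa about the line
axis) the second moments split anisotropically. With R̄₂ = I1(kappa)/I0(kappa)
(the axial mean resultant length, i.e. E[cos 2ψ] of the heading about the
axis), the principal diffusivities are

    D_par  = D_on (1 + R̄₂)   along the line,
    D_perp = D_on (1 − R̄₂)   across it,

which is the exact diffusion limit of the axial walk and reduces correctly to
isotropy as kappa → 0 and to one-dimensional motion as kappa → ∞. Rotating
into grid axes for a line of orientation theta gives the tensor entries
d_xx, d_xy, d_yy. A toward-line bias of concentration kappa_near adds an
advection of magnitude |c| = (alpha_near/tau)·I1(kappa_near)/I0(kappa_near)
pointing at the nearest line.

Three movement models are supported (the candidate behaviours compared in the
analysis): ``no_response`` (isotropic off-line diffusion everywhere),
``aniso`` (anisotropic tensor on lines) and ``aniso_bias`` (additionally the
near-line advection).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movestats import MovementParams, _bessel_ratio
from .synthetic import Landscape, classify_distances

__all__ = [
    "MODELS",
    "CoefficientField",
    "isotropic_D",
    "anisotropic_tensor",
    "bias_advection",
    "build_field",
    "uniform_field",
]

MODELS = ("no_response", "aniso", "aniso_bias")


@dataclass
class CoefficientField:
    """Gridded diffusion tensor and advection field on a regular raster.

    Arrays have shape ``(ny, nx)`` with cell centres at
    ``origin + (i + 0.5) * h``. Units: km²/h for the tensor, km/h for c.
    """

    origin: tuple[float, float]
    h: float
    nx: int
    ny: int
    d_xx: np.ndarray
    d_xy: np.ndarray
    d_yy: np.ndarray
    c_x: np.ndarray
    c_y: np.ndarray
    model: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        shape = (self.ny, self.nx)
        for name in ("d_xx", "d_xy", "d_yy", "c_x", "c_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        self.assert_spd()

    def assert_spd(self) -> None:
        det = self.d_xx * self.d_yy - self.d_xy**2
        if not (np.all(self.d_xx > 0) and np.all(self.d_yy > 0) and np.all(det > 0)):
            raise ValueError("diffusion tensor must be symmetric positive definite")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * self.h
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * self.h
        return x, y

    def center_grid(self) -> np.ndarray:
        """All cell centres as an ``(nx*ny, 2)`` array (row-major in y)."""
        x, y = self.cell_centers()
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])


def isotropic_D(alpha: float, tau: float) -> float:
    """Isotropic diffusion coefficient alpha²/(2·tau) in km²/h.

    ``alpha`` is the exponential mean step length (km), ``tau`` the fix
    interval in hours.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return alpha * alpha / (2.0 * tau)


def anisotropic_tensor(D_on: float, kappa_on: float, theta) -> tuple:
    """Tensor entries (d_xx, d_xy, d_yy) for a line of orientation ``theta``.

    Accepts scalar or array ``theta`` (radians, axial).
    """
    if D_on <= 0:
        raise ValueError("D_on must be positive")
    if kappa_on < 0:
        raise ValueError("kappa_on must be non-negative")
    r2 = float(_bessel_ratio(kappa_on))
    d_par = D_on * (1.0 + r2)
    d_perp = D_on * (1.0 - r2)
    ct, st = np.cos(theta), np.sin(theta)
    d_xx = d_par * ct**2 + d_perp * st**2
    d_yy = d_par * st**2 + d_perp * ct**2
    d_xy = (d_par - d_perp) * st * ct
    return d_xx, d_xy, d_yy


def bias_advection(alpha_near: float, kappa_near: float, tau: float, toward_unit) -> np.ndarray:
    """Advection vector(s) of a toward-line biased walk.

    ``|c| = (alpha_near / tau) * I1(kappa_near)/I0(kappa_near)`` along the
    unit vector(s) pointing at the nearest line. ``toward_unit`` is ``(2,)``
    or ``(n, 2)``; vectors must be unit length.
    """
    if kappa_near < 0:
        raise ValueError("kappa_near must be non-negative")
    u = np.asarray(toward_unit, dtype=float)
    norms = np.linalg.norm(u, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("toward vector must have non-zero length")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("toward vector must be unit length")
    speed = (alpha_near / tau) * float(_bessel_ratio(kappa_near))
    return speed * u


def build_field(
    model: str,
    params: MovementParams,
    landscape: Landscape,
    h: float,
    cross_diffusion: str = "symmetric",
) -> CoefficientField:
    """Rasterise the movement model over the landscape's domain.

    Cells are classed on/near/off by their centre's distance to the nearest
    centreline (same thresholds as fix classification); fields are constant
    within a class. ``cross_diffusion`` selects the across-line diffusivity on
    lines: ``"symmetric"`` uses D_on(1 − R̄₂) (the axial-walk diffusion
    limit), ``"off_perp"`` uses the off-line D instead.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if cross_diffusion not in ("symmetric", "off_perp"):
        raise ValueError("cross_diffusion must be 'symmetric' or 'off_perp'")
    domain = landscape.domain
    nx = round(domain.width / h)
    ny = round(domain.height / h)
    if abs(nx * h - domain.width) > 1e-9 * max(1.0, domain.width) or abs(
        ny * h - domain.height
    ) > 1e-9 * max(1.0, domain.height):
        raise ValueError(f"cell size {h} does not divide the domain edges")

    tau = params.tau_hours
    D_off = isotropic_D(params.alpha_off, tau)
    D_near = isotropic_D(params.alpha_near, tau)
    D_on = isotropic_D(params.alpha_on, tau)

    shape = (ny, nx)
    d_xx = np.full(shape, D_off)
    d_yy = np.full(shape, D_off)
    d_xy = np.zeros(shape)
    c_x = np.zeros(shape)
    c_y = np.zeros(shape)

    if model != "no_response" and not landscape.is_empty:
        x = domain.x0 + (np.arange(nx) + 0.5) * h
        y = domain.y0 + (np.arange(ny) + 0.5) * h
        xx, yy = np.meshgrid(x, y)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        dist, idx, foot = landscape.nearest(centers)
        codes = classify_distances(dist).reshape(shape)

        near = codes == 1
        d_xx[near] = D_near
        d_yy[near] = D_near

        on = codes == 0
        if on.any():
            theta = landscape.orientations[idx].reshape(shape)[on]
            if cross_diffusion == "symmetric":
                txx, txy, tyy = anisotropic_tensor(D_on, params.kappa_on, theta)
            else:  # across-line diffusivity pinned to the off-line value
                r2 = float(_bessel_ratio(params.kappa_on))
                d_par = D_on * (1.0 + r2)
                ct, st = np.cos(theta), np.sin(theta)
                txx = d_par * ct**2 + D_off * st**2
                tyy = d_par * st**2 + D_off * ct**2
                txy = (d_par - D_off) * st * ct
            d_xx[on] = txx
            d_xy[on] = txy
            d_yy[on] = tyy

        if model == "aniso_bias" and params.kappa_near > 0 and near.any():
            vec = foot.reshape(ny, nx, 2)[near] - centers.reshape(ny, nx, 2)[near]
            norms = np.linalg.norm(vec, axis=1)
            ok = norms > 1e-12
            unit = np.zeros_like(vec)
            unit[ok] = vec[ok] / norms[ok, None]
            c = np.zeros_like(vec)
            c[ok] = bias_advection(params.alpha_near, params.kappa_near, tau, unit[ok])
            c_x[near] = c[:, 0]
            c_y[near] = c[:, 1]

    return CoefficientField(
        (domain.x0, domain.y0), h, nx, ny, d_xx, d_xy, d_yy, c_x, c_y, model,
        meta={"cross_diffusion": cross_diffusion, "tau_h": tau},
    )


def uniform_field(
    D: float,
    origin: tuple[float, float],
    h: float,
    nx: int,
    ny: int,
) -> CoefficientField:
    """Spatially uniform isotropic field — handy for analytic benchmarks."""
    shape = (ny, nx)
    z = np.zeros(shape)
    return CoefficientField(
        origin, h, nx, ny, np.full(shape, D), z.copy(), np.full(shape, D),
        z.copy(), z.copy(), "no_response",
    )
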