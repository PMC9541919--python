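"""Blood rheology: strain rate from the masked velocity gradient and a
hematocrit-dependent shear-thinning viscosity.

Blood is treated as an incompressible fluid of density 1025 kg/m^3 whose
apparent viscosity falls with shear rate.  The shear-thinning law is a
Carreau--Yasuda model

    mu(gdot) = mu_inf + (mu_0 - mu_inf) * [1 + (lambda * gdot)^a]^((n - 1) / a)

with both asymptotic viscosities scaled monotonically with the subject's
hematocrit (an exponential factor ``exp(k * (hct - hct_ref))``, the standard
leading-order dependence of whole-blood viscosity on red-cell volume
fraction).  The default constants are the widely used whole-blood Carreau
fit (mu_0 = 56 mPa s, mu_inf = 3.45 mPa s, lambda = 3.313 s, n = 0.3568,
a = 2) referenced to hct = 0.45; every constant is config-overridable and a
Newtonian model is provided for analytic verification work.

Shear rate uses the convention  gdot = sqrt(2 S : S)  with S the symmetric
strain-rate tensor, which reduces to |k| for the simple shear v_x = k*y.
(The alternative sqrt(S:S / 2) convention differs by a factor of 2 and
sqrt(2 S:S) by sqrt(2) from the second-invariant form; the chosen one is
the one under which a Newtonian fluid dissipates Phi = mu * gdot^2.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ValidationError

#: Blood density used throughout, kg/m^3.
BLOOD_DENSITY = 1025.0


@dataclass
class RheologyParams:
    """Constitutive parameters for intraventricular blood.

    ``model`` is either ``"carreau_yasuda_hct"`` (shear-thinning with
    hematocrit scaling) or ``"newtonian"`` (constant ``newtonian_mu``).
    Viscosities in Pa s, ``relaxation_time`` in s, the rest dimensionless.
    ``hct_sensitivity`` is the exponential rate of the hematocrit scaling
    applied to both asymptotic viscosities.
    """

    density: float = BLOOD_DENSITY
    model: str = "carreau_yasuda_hct"
    mu_inf: float = 3.45e-3
    mu_zero: float = 5.6e-2
    relaxation_time: float = 3.313
    power_index: float = 0.3568
    transition: float = 2.0
    hct_reference: float = 0.45
    hct_sensitivity: float = 2.5
    newtonian_mu: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.model not in ("carreau_yasuda_hct", "newtonian"):
            raise ValidationError(f"unknown rheology model {self.model!r}")
        if self.density <= 0:
            raise ValidationError("density must be positive")
        for name in ("mu_inf", "mu_zero", "relaxation_time", "power_index",
                     "transition", "newtonian_mu"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.mu_zero < self.mu_inf:
            raise ValidationError("mu_zero must be >= mu_inf")


def masked_derivative(field: np.ndarray, mask: np.ndarray, axis: int) -> tuple:
    """d(field)/d(index) along ``axis``, restricted to the mask.

    Central differences where both neighbours are in the mask; second-order
    one-sided (3-point) differences at mask boundaries when two inward
    neighbours exist, first-order otherwise.  Voxels with no in-mask
    neighbour along the axis get derivative 0 and are flagged.

    Returns ``(deriv, no_neighbour)`` in units of field-units per voxel.
    """
    f = np.asarray(field, dtype=float)
    m = mask.astype(bool)

    def shift(arr, n):
        out = np.zeros_like(arr) if arr.dtype != bool else np.zeros_like(arr)
        src = [slice(None)] * arr.ndim
        dst = [slice(None)] * arr.ndim
        if n > 0:
            src[axis] = slice(n, None)
            dst[axis] = slice(None, -n)
        elif n < 0:
            src[axis] = slice(None, n)
            dst[axis] = slice(-n, None)
        else:
            return arr.copy()
        out[tuple(dst)] = arr[tuple(src)]
        return out

    fp1, fm1 = shift(f, 1), shift(f, -1)
    fp2, fm2 = shift(f, 2), shift(f, -2)
    mp1, mm1 = shift(m, 1), shift(m, -1)
    mp2, mm2 = shift(m, 2), shift(m, -2)

    deriv = np.zeros_like(f)
    central = mp1 & mm1
    fwd2 = ~mm1 & mp1 & mp2
    fwd1 = ~mm1 & mp1 & ~mp2
    bwd2 = ~mp1 & mm1 & mm2
    bwd1 = ~mp1 & mm1 & ~mm2
    none_ = ~mp1 & ~mm1

    deriv[central] = 0.5 * (fp1[central] - fm1[central])
    deriv[fwd2] = 0.5 * (-3.0 * f[fwd2] + 4.0 * fp1[fwd2] - fp2[fwd2])
    deriv[fwd1] = fp1[fwd1] - f[fwd1]
    deriv[bwd2] = 0.5 * (3.0 * f[bwd2] - 4.0 * fm1[bwd2] + fm2[bwd2])
    deriv[bwd1] = f[bwd1] - fm1[bwd1]

    deriv[~m] = 0.0
    return deriv, (none_ & m)


def velocity_gradient(
    velocity: np.ndarray,
    mask: np.ndarray,
    spacing: np.ndarray,
    axes: np.ndarray = None,
    return_flags: bool = False,
):
    """Per-voxel velocity-gradient tensor L[i, j] = dv_i/dx_j in 1/s.

    ``velocity`` is one frame (X, Y, Z, 3) of world-frame components in m/s,
    ``spacing`` in mm, ``axes`` the grid direction cosines (world
    derivatives are assembled as  d/dx = axes @ diag(1/spacing) d/d(index)).
    Outside the mask the tensor is zero.  With ``return_flags`` a boolean
    volume marks voxels where the mask was too thin along some axis to form
    any difference (low-confidence, derivative taken as 0 there).
    """
    spacing = np.asarray(spacing, dtype=float)
    A = np.eye(3) if axes is None else np.asarray(axes, dtype=float)
    shape = velocity.shape[:3]
    L = np.zeros(shape + (3, 3))
    thin = np.zeros(shape, dtype=bool)
    # index-space derivatives, scaled to per-metre (spacing is mm)
    dv = np.zeros(shape + (3, 3))  # dv[i, k] = dv_i/d(index_k) / spacing_k
    for i in range(3):
        for k in range(3):
            d, flag = masked_derivative(velocity[..., i], mask, axis=k)
            dv[..., i, k] = d / (spacing[k] * 1e-3)
            thin |= flag
    # world gradient: dv_i/dx_j = sum_k A[j, k] * dv[i, k]
    L = np.einsum("jk,...ik->...ij", A, dv)
    L[~mask] = 0.0
    if return_flags:
        return L, thin
    return L


def strain_rate_tensor(gradient: np.ndarray) -> np.ndarray:
    """Symmetric part S = (L + L^T) / 2 of the velocity-gradient tensor."""
    return 0.5 * (gradient + np.swapaxes(gradient, -1, -2))


def shear_rate(gradient: np.ndarray) -> np.ndarray:
    """Scalar shear rate gdot = sqrt(2 S:S) in 1/s."""
    S = strain_rate_tensor(gradient)
    return np.sqrt(2.0 * np.einsum("...ij,...ij->...", S, S))


def viscosity(
    gdot: np.ndarray,
    hematocrit: float,
    params: RheologyParams = None,
) -> np.ndarray:
    """Apparent viscosity field mu(gdot, hct) in Pa s.

    The Carreau--Yasuda asymptotes are scaled by
    ``exp(hct_sensitivity * (hct - hct_reference))``; the bound
    mu_inf_scaled <= mu <= mu_zero_scaled holds for every shear rate.
    """
    params = params or RheologyParams()
    if not 0.0 <= hematocrit <= 1.0:
        raise ValidationError("hematocrit must be in [0, 1]")
    gdot = np.asarray(gdot, dtype=float)
    if params.model == "newtonian":
        return np.full_like(gdot, params.newtonian_mu)
    scale = np.exp(params.hct_sensitivity * (hematocrit - params.hct_reference))
    mu0 = params.mu_zero * scale
    mui = params.mu_inf * scale
    lam, a, n = params.relaxation_time, params.transition, params.power_index
    return mui + (mu0 - mui) * (1.0 + (lam * gdot) ** a) ** ((n - 1.0) / a)
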