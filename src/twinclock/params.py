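"""Canonical parameterization of the structural twin model.

The generative / fitted model has three phenotypes per twin: childhood IQ
(X), a latent DNA-methylation-age factor (M), and adult IQ (Y). Each carries
an ACE decomposition (additive genetic A, shared environment C, nonshared
environment E), with the genetic component correlated 1.0 across MZ co-twins
and 0.5 across DZ co-twins. Family-level childhood SES (S, centered) enters
every phenotype linearly, and moderates the M -> Y regression through an
interaction coefficient acting on the product S * M.

Structural equations, per twin j in a family with centered SES ``s``::

    X_j = mu_x + b_sx*s + A_Xj + C_X + E_Xj
    M_j = mu_m + b_sm*s + b_p2*X_j + b_a2*A_Xj + b_c2*C_X + A_Mj + C_M + E_Mj
    Y_j = mu_y + b_sy*s + b_p1*X_j + (b_p3 + b_int*s)*M_j
          + b_a1*A_Xj + b_c1*C_X + b_a3*A_Mj + b_c3*C_M + A_Yj + C_Y + E_Yj

b_p1/b_p2/b_p3 are the phenotypic regressions conditional on the genetic and
shared-environmental paths (b_a*, b_c*); in the co-twin-control reading,
b_p3 is the quasi-causal effect of age acceleration on IQ change.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .errors import ConfigError

#: Canonical parameter order used by the likelihood machinery.
PARAM_NAMES: tuple[str, ...] = (
    "mu_x", "mu_m", "mu_y",
    "b_sx", "b_sm", "b_sy",
    "b_p1", "b_p2", "b_p3", "b_int",
    "b_a1", "b_c1", "b_a2", "b_c2", "b_a3", "b_c3",
    "va_x", "vc_x", "ve_x",
    "va_m", "vc_m", "ve_m",
    "va_y", "vc_y", "ve_y",
)

VARIANCE_NAMES = tuple(n for n in PARAM_NAMES if n[0] == "v")


@dataclass
class StructuralParams:
    """Means, regressions and ACE variance components of the path model."""

    mu_x: float = 0.0
    mu_m: float = 0.0
    mu_y: float = 0.0
    b_sx: float = 0.0
    b_sm: float = 0.0
    b_sy: float = 0.0
    b_p1: float = 0.0
    b_p2: float = 0.0
    b_p3: float = 0.0
    b_int: float = 0.0
    b_a1: float = 0.0
    b_c1: float = 0.0
    b_a2: float = 0.0
    b_c2: float = 0.0
    b_a3: float = 0.0
    b_c3: float = 0.0
    va_x: float = 1.0
    vc_x: float = 0.0
    ve_x: float = 1.0
    va_m: float = 1.0
    vc_m: float = 0.0
    ve_m: float = 1.0
    va_y: float = 1.0
    vc_y: float = 0.0
    ve_y: float = 1.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StructuralParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def replace(self, **kwargs) -> "StructuralParams":
        return replace(self, **kwargs)

    def validate(self, allow_negative_vc: bool = False) -> None:
        for name in VARIANCE_NAMES:
            value = getattr(self, name)
            if name.startswith("vc_") and allow_negative_vc:
                continue
            if value < 0:
                raise ConfigError(name, f"variance must be nonnegative, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def reference_structural_params() -> StructuralParams:
    """Generating truth for parameter-recovery studies.

    Coefficients are on the rescaled analysis scale (IQ-type variables on a
    compressed metric, SES standardized to SD 1) on which the quasi-causal
    model is typically reported: childhood IQ carries forward strongly
    (b_p1 = 0.48), accelerated DNAm age predicts negative IQ change
    (b_p3 = -0.18) with the effect attenuated at higher SES (b_int = 0.07),
    and lower childhood SES predicts accelerated DNAm age (b_sm = -0.67).
    Shared-environment variances of M and Y are zero (boundary estimates),
    so b_c3 is fixed at zero as well.
    """
    return StructuralParams(
        mu_x=0.0, mu_m=0.0, mu_y=0.0,
        b_sx=0.56, b_sm=-0.67, b_sy=0.18,
        b_p1=0.48, b_p2=0.38, b_p3=-0.18, b_int=0.07,
        b_a1=0.16, b_c1=0.80, b_a2=-0.78, b_c2=0.30, b_a3=0.13, b_c3=0.0,
        va_x=1.06, vc_x=0.21, ve_x=0.23,
        va_m=1.73, vc_m=0.0, ve_m=0.80,
        va_y=0.43, vc_y=0.0, ve_y=0.23,
    )
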