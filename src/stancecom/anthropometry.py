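"""Segment inertial parameters of the single-leg-stance rigid-link model.

The body is split into five segments: the stance foot (resting on the
plate), the stance leg and the upper body (the "main system", a double
inverted pendulum pivoting at the ankle and stance hip), and the thigh and
lower leg + foot of the raised leg (the "subsystem", a two-link chain
hanging from the non-stance hip).  Every segment mass, length, COM height
and moment of inertia is a fixed multiple of the subject's mass ``M`` [kg],
height ``H`` [m], or ``M*H**2``, taken from standard anthropometric
regression tables.

The coefficient table below is the single source of truth for the model
geometry; per-segment overrides are deliberately not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

STANDARD_GRAVITY = 9.80665
"""Standard acceleration of free fall [m/s^2]."""

#: (field name, coefficient, scale) — scale is one of "M", "H", "MH2".
_TABLE: tuple[tuple[str, float, str], ...] = (
    # upper body (m2)
    ("m_m2", 0.656, "M"),
    ("J_m2x", 1.30e-2, "MH2"),
    ("J_m2y", 1.10e-2, "MH2"),
    ("l_m2", 0.169, "H"),
    ("L_m2", 0.406, "H"),
    # stance leg (m1)
    ("m_m1", 0.161, "M"),
    ("J_m1x", 2.53e-3, "MH2"),
    ("J_m1y", 2.56e-3, "MH2"),
    ("l_m1", 0.302, "H"),
    ("L_m1", 0.491, "H"),
    # stance foot
    ("m_f", 0.011, "M"),
    ("L_f", 0.039, "H"),
    # non-stance thigh (s1)
    ("m_s1", 0.110, "M"),
    ("J_s1x", 4.81e-4, "MH2"),
    ("J_s1y", 5.10e-4, "MH2"),
    ("J_s1z", 1.53e-4, "MH2"),
    ("l_s1", 0.129, "H"),
    ("L_s1", 0.245, "H"),
    # non-stance lower leg + foot (s2)
    ("m_s2", 0.062, "M"),
    ("J_s2x", 4.86e-4, "MH2"),
    ("J_s2y", 4.92e-4, "MH2"),
    ("J_s2z", 2.89e-4, "MH2"),
    ("l_s2", 0.155, "H"),
    ("L_s2", 0.285, "H"),
    # whole body
    ("l_m", 0.589, "H"),
    ("w", 0.100, "H"),
)


@dataclass(frozen=True)
class SubjectProfile:
    """Subject anthropometry and stance side.

    Parameters
    ----------
    height : float
        Standing height H [m].
    mass : float
        Body mass M [kg].
    stance_side : {"right", "left"}
        Which leg the subject stands on.  All frontal-plane sign rules
        (the ±w terms) key off this.
    """

    height: float
    mass: float
    stance_side: str = "right"

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise ValueError(f"height must be positive, got {self.height!r}")
        if not (self.mass > 0):
            raise ValueError(f"mass must be positive, got {self.mass!r}")
        if self.stance_side not in ("right", "left"):
            raise ValueError(
                f"stance_side must be 'right' or 'left', got {self.stance_side!r}"
            )


@dataclass(frozen=True)
class BodyParams:
    """All derived segment parameters of the rigid-link model (SI units).

    Masses ``m_*`` [kg], segment lengths ``L_*`` [m], COM heights from the
    distal (bottom) end ``l_*`` [m], moments of inertia about the segment
    COM ``J_*`` [kg m^2], inter-hip distance ``w`` [m], whole-body COM
    height ``l_m`` [m], ankle height ``L_f`` [m] and gravity ``g`` [m/s^2].
    """

    m_m2: float
    J_m2x: float
    J_m2y: float
    l_m2: float
    L_m2: float
    m_m1: float
    J_m1x: float
    J_m1y: float
    l_m1: float
    L_m1: float
    m_f: float
    L_f: float
    m_s1: float
    J_s1x: float
    J_s1y: float
    J_s1z: float
    l_s1: float
    L_s1: float
    m_s2: float
    J_s2x: float
    J_s2y: float
    J_s2z: float
    l_s2: float
    L_s2: float
    l_m: float
    w: float
    g: float = STANDARD_GRAVITY

    @property
    def m_main(self) -> float:
        """Mass of the main-system pendulum (stance leg + upper body) [kg]."""
        return self.m_m1 + self.m_m2

    @property
    def m_sub(self) -> float:
        """Mass of the swing-leg subsystem (thigh + lower leg) [kg]."""
        return self.m_s1 + self.m_s2

    @property
    def m_moving(self) -> float:
        """Mass of the four moving segments (everything but the stance foot)."""
        return self.m_main + self.m_sub

    @property
    def total_mass(self) -> float:
        return self.m_moving + self.m_f

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValueError(f"BodyParams.{f.name} must be positive, got {v!r}")
        for lo, hi in (("l_m1", "L_m1"), ("l_m2", "L_m2"),
                       ("l_s1", "L_s1"), ("l_s2", "L_s2")):
            if not getattr(self, lo) < getattr(self, hi):
                raise ValueError(f"expected {lo} < {hi}")


def compute_body_params(
    profile: SubjectProfile, g: float = STANDARD_GRAVITY
) -> BodyParams:
    """Derive every segment parameter from subject height and mass.

    Each parameter is a fixed coefficient times ``M``, ``H`` or ``M*H**2``.
    The five segment mass fractions sum to exactly 1, so segment masses
    conserve total body mass to machine precision.

    Parameters
    ----------
    profile : SubjectProfile
    g : float, optional
        Gravitational acceleration [m/s^2]; defaults to standard gravity.

    Returns
    -------
    BodyParams
    """
    M, H = profile.mass, profile.height
    scale = {"M": M, "H": H, "MH2": M * H * H}
    values = {name: coeff * scale[kind] for name, coeff, kind in _TABLE}
    return BodyParams(g=g, **values)
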