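"""Empirical blood rheology: effective viscosity, Fahraeus effect, phase separation.

Blood in microvessels is not a continuum fluid: red blood cells raise the
effective viscosity in a strongly diameter-dependent way
(Fahraeus–Lindqvist effect), travel faster than the bulk flow so that the
tube hematocrit is below the discharge hematocrit (Fahraeus effect), and
partition unevenly between the daughters of a divergent bifurcation, the
higher-flow daughter receiving a disproportionate share of the cells
(phase separation, also called the Zweifach–Fung effect).

All three effects are represented by the standard in vitro empirical laws
of the Pries–Secomb family (Pries, Neuhaus & Gaehtgens 1992 viscosity fit;
Pries et al. 1990 tube/discharge hematocrit relation; Pries et al.
1989/1990 bifurcation partitioning).  Diameters are in µm, hematocrits are
fractions.  The coefficient set is identified by ``LAW_VERSION`` so that
provenance output can pin it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyParams",
    "relative_effective_viscosity",
    "tube_from_discharge_hematocrit",
    "discharge_hematocrit",
    "phase_separation",
    "fahraeus_velocity_ratio",
]

LAW_VERSION = "pries1990_invitro"

#: discharge hematocrit is clipped to this value inside the viscosity law;
#: the empirical fit is singular at H_d -> 1 for diameters with a negative
#: shape exponent and was calibrated well below packed-cell fractions
_H_CLIP = 0.99


@dataclass(frozen=True)
class RheologyParams:
    """Parameters of the empirical laws.

    plasma_viscosity : dynamic plasma viscosity µ, Pa·s
    single_file_diameter_threshold : µm; at divergent bifurcations whose
        parent is wider than this, the empirical partitioning equations
        apply; below it RBCs travel in single file and follow the largest
        pressure force.
    law_version : identifier of the coefficient set.
    """

    plasma_viscosity: float = 1.2e-3
    single_file_diameter_threshold: float = 10.0
    law_version: str = LAW_VERSION

    def __post_init__(self):
        if not self.plasma_viscosity > 0:
            raise ValueError("plasma_viscosity must be > 0")
        if not self.single_file_diameter_threshold > 0:
            raise ValueError("single_file_diameter_threshold must be > 0")


def _mu_star_45(d):
    """In vitro relative viscosity at discharge hematocrit 0.45."""
    return 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)


def _shape_exponent(d):
    frac = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + np.exp(-0.075 * d)) * (frac - 1.0) + frac


def relative_effective_viscosity(diameter, discharge_hematocrit, params=None):
    """Relative effective viscosity µ_rel(D, H_d), dimensionless.

    Equals 1 in the plasma limit (H_d = 0), increases with hematocrit, and
    as a function of diameter at fixed hematocrit shows the
    Fahraeus–Lindqvist minimum near 7–10 µm.  Vectorised in both arguments.
    """
    d = np.asarray(diameter, dtype=np.float64)
    h = np.asarray(discharge_hematocrit, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1]")
    h = np.minimum(h, _H_CLIP)
    c = _shape_exponent(d)
    mu45 = _mu_star_45(d)
    with np.errstate(invalid="ignore"):
        frac = ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)
    mu = 1.0 + (mu45 - 1.0) * frac
    return mu if mu.ndim else float(mu)


def _fahraeus_factor(d):
    """F(D) in H_t/H_d = H_d + (1 - H_d) F(D); the low-hematocrit limit.

    The raw fit exceeds 1 below ~2.6 µm (an extrapolation artifact that
    would make cells slower than plasma); it is floored at 1, i.e. tube
    and discharge hematocrit coincide in the narrowest lumens where cells
    fill the cross-section and move with the plasma.
    """
    d = np.asarray(d, dtype=np.float64)
    return np.minimum(1.0 + 1.7 * np.exp(-0.415 * d) - 0.6 * np.exp(-0.011 * d), 1.0)


def tube_from_discharge_hematocrit(discharge_hematocrit, diameter):
    """Forward Fahraeus relation: tube hematocrit given discharge hematocrit."""
    h = np.asarray(discharge_hematocrit, dtype=np.float64)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1]")
    f = _fahraeus_factor(diameter)
    ht = h * (h + (1.0 - h) * f)
    return ht if ht.ndim else float(ht)


def discharge_hematocrit(tube_hematocrit, diameter):
    """Invert the Fahraeus relation: discharge hematocrit from tube hematocrit.

    RBCs travel faster than the bulk flow, so the returned value is >= the
    tube hematocrit; it is the identity at 0 and 1.  The forward relation
    H_t = H_d (H_d + (1 - H_d) F(D)) is quadratic in H_d and inverted in
    closed form (the root inside [0, 1]).
    """
    ht = np.asarray(tube_hematocrit, dtype=np.float64)
    if np.any((ht < 0) | (ht > 1)):
        raise ValueError("tube hematocrit must lie in [0, 1]")
    f = _fahraeus_factor(diameter)
    f = np.broadcast_to(f, ht.shape) if ht.ndim else f
    a = 1.0 - f  # quadratic coefficient: a H_d^2 + f H_d - H_t = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(f * f + 4.0 * a * ht)
        hd_quad = (disc - f) / (2.0 * a)
    hd_lin = ht / np.where(f == 0, 1.0, f)
    hd = np.where(np.abs(a) < 1e-12, hd_lin, hd_quad)
    hd = np.clip(hd, ht, 1.0)  # guard round-off; H_d >= H_t always
    return hd if hd.ndim else float(hd)


def fahraeus_velocity_ratio(tube_hematocrit, diameter):
    """RBC velocity / bulk velocity = H_d / H_t (1/F(D) in the dilute limit)."""
    ht = np.asarray(tube_hematocrit, dtype=np.float64)
    hd = discharge_hematocrit(ht, diameter)
    dilute = 1.0 / _fahraeus_factor(diameter)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ht > 0, hd / np.where(ht > 0, ht, 1.0), dilute)
    return ratio if ratio.ndim else float(ratio)


def _logit(x):
    return np.log(x / (1.0 - x))


def phase_separation(
    parent_diameter,
    parent_discharge_hematocrit,
    daughter_flow_fraction,
    daughter_diameter,
    other_daughter_diameter,
):
    """RBC flux fraction entering one daughter of a divergent bifurcation.

    Empirical in vitro partitioning law: with X0 = 0.964 (1 - H_d)/D_f, a
    daughter receiving a blood flow fraction below X0 receives no RBCs at
    all, one above 1 - X0 receives them all, and in between

        logit(F_rbc) = A + B logit((F_blood - X0)/(1 - 2 X0)),

    B = 1 + 6.98 (1 - H_d)/D_f > 1 (amplification: the higher-flow daughter
    is overloaded with cells) and A = -13.29 [(Da²/Db²-1)/(Da²/Db²+1)]
    (1 - H_d)/D_f (a wider daughter attracts cells at equal flow).
    Diameters in µm.  The complementary daughter receives 1 minus the
    returned fraction.  Only valid for parents above the single-file
    threshold; narrower bifurcations are routed cell-by-cell by pressure
    force (see :mod:`capnet.transport`).
    """
    df = float(parent_diameter)
    hd = float(parent_discharge_hematocrit)
    fqb = np.asarray(daughter_flow_fraction, dtype=np.float64)
    if np.any((fqb < 0) | (fqb > 1)):
        raise ValueError("flow fraction must lie in [0, 1]")
    if not 0 <= hd <= 1:
        raise ValueError("hematocrit must lie in [0, 1]")
    hd = min(hd, _H_CLIP)
    x0 = 0.964 * (1.0 - hd) / df
    x0 = min(x0, 0.499)  # degenerate only for sub-µm parents
    b = 1.0 + 6.98 * (1.0 - hd) / df
    ratio2 = (float(daughter_diameter) / float(other_daughter_diameter)) ** 2
    a = -13.29 * ((ratio2 - 1.0) / (ratio2 + 1.0)) * (1.0 - hd) / df

    inner = (fqb - x0) / (1.0 - 2.0 * x0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logit_fe = a + b * _logit(np.clip(inner, 1e-15, 1.0 - 1e-15))
        fe = 1.0 / (1.0 + np.exp(-logit_fe))
    fe = np.where(fqb <= x0, 0.0, np.where(fqb >= 1.0 - x0, 1.0, fe))
    return fe if fe.ndim else float(fe)
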