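"""Hyperelastic material laws for the breast soft tissues.

Strain energy per unit reference volume, decoupled into an isochoric part
in the barred invariants of the left Cauchy-Green tensor and a volumetric
penalty:

* Neo-Hookean:      W = mu/2 (I1b - 3) + (1/d)(J - 1)^2
* Mooney-Rivlin-5:  W = sum_{(i,j)} C_ij (I1b - 3)^i (I2b - 3)^j
                        + (1/d)(J - 1)^2,   (i,j) in {10, 01, 11, 20, 02}

with mu = E / (2(1+v)) and d = 6(1-2v)/E the incompressibility parameter.
For the Mooney-Rivlin material (adipose tissue) d is derived from its
small-strain effective modulus E_eff = 2 (1+v) * 2 (C10 + C01).

Units: stresses and moduli kPa, density kg/mm^3, lengths mm (the mm-kg-s
system, in which 1 unit of stress is exactly 1 kPa).

All tensor functions accept arrays of deformation gradients with leading
batch dimensions and are valid for complex perturbations of F, so
derivatives can be taken by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DENSITY_KGM3_TO_SOLVER = 1e-9  # kg/m^3 -> kg/mm^3

MR_TERMS = ("C10", "C01", "C11", "C20", "C02")
# printed five-parameter Mooney-Rivlin coefficients for adipose tissue, kPa
ADIPOSE_MR = {"C10": 0.31, "C01": 0.3, "C11": 2.25, "C20": 3.8, "C02": 4.72}


class IncompressibleLimitError(ValueError):
    """v = 0.5 requested: the volumetric penalty 1/d is undefined."""


class InvertedElementError(ValueError):
    """det F <= 0 encountered."""


def convert_E_nu(E: float, v: float) -> tuple:
    """Shear modulus mu = E/(2(1+v)) and incompressibility d = 6(1-2v)/E."""
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not 0.0 < v < 0.5:
        if v == 0.5:
            raise IncompressibleLimitError(
                "v = 0.5 gives d = 0; the penalty 1/d is undefined")
        raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {v}")
    return E / (2.0 * (1.0 + v)), 6.0 * (1.0 - 2.0 * v) / E


@dataclass
class ConstitutiveModel:
    """A material: law kind, parameters and density.

    Construct via :func:`neo_hookean` or :func:`mooney_rivlin5`.
    """

    kind: str                       # "neo_hookean" | "mooney_rivlin_5"
    E: float | None = None          # kPa (neo_hookean)
    v: float = 0.49
    coefficients: dict = field(default_factory=dict)   # kPa (mooney_rivlin_5)
    density: float = 1050.0 * DENSITY_KGM3_TO_SOLVER   # kg/mm^3
    mu: float = field(init=False)
    d_incomp: float = field(init=False)                # 1/kPa

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.kind == "neo_hookean":
            self.mu, self.d_incomp = convert_E_nu(self.E, self.v)
        elif self.kind == "mooney_rivlin_5":
            c = {k: float(self.coefficients.get(k, 0.0)) for k in MR_TERMS}
            if not all(np.isfinite(list(c.values()))):
                raise ValueError("Mooney-Rivlin coefficients must be finite")
            if c["C10"] + c["C01"] <= 0:
                raise ValueError("C10 + C01 must be positive")
            self.coefficients = c
            self.mu = 2.0 * (c["C10"] + c["C01"])
            e_eff = 2.0 * self.mu * (1.0 + self.v)
            _, self.d_incomp = convert_E_nu(e_eff, self.v)
        else:
            raise ValueError(f"unknown material kind {self.kind!r}")


def neo_hookean(E: float, v: float = 0.49,
                density_kgm3: float = 1050.0) -> ConstitutiveModel:
    return ConstitutiveModel(kind="neo_hookean", E=E, v=v,
                             density=density_kgm3 * DENSITY_KGM3_TO_SOLVER)


def mooney_rivlin5(coefficients: dict | None = None, v: float = 0.49,
                   density_kgm3: float = 950.0) -> ConstitutiveModel:
    return ConstitutiveModel(kind="mooney_rivlin_5",
                             coefficients=dict(coefficients or ADIPOSE_MR), v=v,
                             density=density_kgm3 * DENSITY_KGM3_TO_SOLVER)


def small_strain_modulus(model: ConstitutiveModel) -> float:
    """Effective small-strain Young's modulus, 2 mu_eff (1+v), kPa."""
    return 2.0 * model.mu * (1.0 + model.v)


def material_table(skin_density_kgm3: float = 1050.0) -> dict:
    """Default material assignment per mesh component.

    Neo-Hookean stiffnesses: skin 500 kPa, soft layer / pectoralis /
    glandular tissue 10 kPa, Cooper's ligaments 100 kPa; adipose tissue is
    the five-parameter Mooney-Rivlin material.  v = 0.49 throughout.
    Densities (kg/m^3): adipose 950, ligament 1040, gland 1070, pectoralis
    and soft layer 1050; skin density is not established in the literature
    used here and is configurable (default 1050).
    """
    return {
        "skin": neo_hookean(500.0, density_kgm3=skin_density_kgm3),
        "soft_layer": neo_hookean(10.0, density_kgm3=1050.0),
        "pectoralis": neo_hookean(10.0, density_kgm3=1050.0),
        "ligament": neo_hookean(100.0, density_kgm3=1040.0),
        "gland": neo_hookean(10.0, density_kgm3=1070.0),
        "adipose": mooney_rivlin5(density_kgm3=950.0),
    }


def save_material_table(path, table: dict) -> None:
    """Write a material table as YAML (kPa / kg/m^3 units in the file)."""
    doc = {"units": {"modulus": "kPa", "density": "kg/m^3"}, "materials": {}}
    for comp, m in table.items():
        entry = {"kind": m.kind, "v": m.v,
                 "density": m.density / DENSITY_KGM3_TO_SOLVER}
        if m.kind == "neo_hookean":
            entry["E"] = m.E
        else:
            entry["coefficients"] = dict(m.coefficients)
        doc["materials"][comp] = entry
    with open(path, "w") as fh:
        fh.write("# breastfem material table; moduli in kPa, densities in kg/m^3\n")
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_material_table(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for comp, e in doc["materials"].items():
        if e["kind"] == "neo_hookean":
            out[comp] = neo_hookean(e["E"], v=e["v"], density_kgm3=e["density"])
        else:
            out[comp] = mooney_rivlin5(e["coefficients"], v=e["v"],
                                       density_kgm3=e["density"])
    return out


# -- tensor algebra (batched, complex-safe) --------------------------------

def det3(A):
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def inv3(A):
    d = det3(A)
    adj = np.empty_like(A)
    adj[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    adj[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    adj[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    adj[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    adj[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    adj[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    adj[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    adj[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    adj[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return adj / d[..., None, None]


def _invariants(F):
    """J, B, I1b, I2b, Finv_T for batched (complex-capable) F."""
    J = det3(F)
    if not np.iscomplexobj(F) and np.any(J.real <= 0):
        raise InvertedElementError("deformation gradient with det F <= 0")
    B = F @ np.swapaxes(F, -1, -2)
    trB = np.trace(B, axis1=-2, axis2=-1)
    trB2 = np.trace(B @ B, axis1=-2, axis2=-1)
    I1b = J ** (-2.0 / 3.0) * trB
    I2b = J ** (-4.0 / 3.0) * 0.5 * (trB ** 2 - trB2)
    return J, B, I1b, I2b, np.swapaxes(inv3(F), -1, -2)


@dataclass
class DeformationPoint:
    """Kinematic state at a material point: F, J and barred invariants."""

    F: np.ndarray
    J: float
    B_bar: np.ndarray
    I1_bar: float
    I2_bar: float

    @classmethod
    def from_F(cls, F) -> "DeformationPoint":
        F = np.asarray(F, dtype=float)
        J, B, I1b, I2b, _ = _invariants(F)
        B_bar = J ** (-2.0 / 3.0) * B
        return cls(F=F, J=float(J), B_bar=B_bar, I1_bar=float(I1b), I2_bar=float(I2b))


def _iso_derivatives(model: ConstitutiveModel, I1b, I2b):
    """dW/dI1b and dW/dI2b."""
    if model.kind == "neo_hookean":
        return 0.5 * model.mu * np.ones_like(I1b), np.zeros_like(I1b)
    c = model.coefficients
    a, b = I1b - 3.0, I2b - 3.0
    W1 = c["C10"] + c["C11"] * b + 2.0 * c["C20"] * a
    W2 = c["C01"] + c["C11"] * a + 2.0 * c["C02"] * b
    return W1, W2


def strain_energy(model: ConstitutiveModel, p) -> float | np.ndarray:
    """Strain-energy density W (kPa) at a deformation point or batch of F."""
    F = p.F if isinstance(p, DeformationPoint) else np.asarray(p)
    J, _, I1b, I2b, _ = _invariants(F)
    if model.kind == "neo_hookean":
        W = 0.5 * model.mu * (I1b - 3.0)
    else:
        c = model.coefficients
        a, b = I1b - 3.0, I2b - 3.0
        W = (c["C10"] * a + c["C01"] * b + c["C11"] * a * b
             + c["C20"] * a ** 2 + c["C02"] * b ** 2)
    W = W + (1.0 / model.d_incomp) * (J - 1.0) ** 2
    return float(W.real) if np.isscalar(J) or J.ndim == 0 else W


def pk1_iso_stress(model: ConstitutiveModel, F) -> np.ndarray:
    """Isochoric part of the first Piola-Kirchhoff stress (kPa), batched,
    complex-safe."""
    F = np.asarray(F)
    J, B, I1b, I2b, FinvT = _invariants(F)
    W1, W2 = _iso_derivatives(model, I1b, I2b)
    Jm23 = J ** (-2.0 / 3.0)
    dI1 = 2.0 * (Jm23[..., None, None] * F - (I1b / 3.0)[..., None, None] * FinvT)
    dI2 = 2.0 * ((I1b * Jm23)[..., None, None] * F
                 - (Jm23 ** 2)[..., None, None] * (B @ F)
                 - (2.0 * I2b / 3.0)[..., None, None] * FinvT)
    return W1[..., None, None] * dI1 + W2[..., None, None] * dI2


def pk1_stress(model: ConstitutiveModel, F) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF (kPa), batched, complex-safe."""
    F = np.asarray(F)
    J = det3(F)
    FinvT = np.swapaxes(inv3(F), -1, -2)
    Pvol = (2.0 / model.d_incomp) * ((J - 1.0) * J)[..., None, None] * FinvT
    return pk1_iso_stress(model, F) + Pvol


def pk1_local_tangent(model: ConstitutiveModel, F, pressure,
                      h: float = 1e-30) -> np.ndarray:
    """d/dF of [P_iso(F) + p J F^-T] at frozen pressure p (batched).

    Used by mean-dilatation assembly, where p = U'(theta) is held by the
    patch and its variation enters through a separate rank-one coupling.
    """
    F = np.asarray(F, dtype=float)
    p = np.asarray(pressure)

    def local_P(Fc):
        J = det3(Fc)
        FinvT = np.swapaxes(inv3(Fc), -1, -2)
        return pk1_iso_stress(model, Fc) + p[..., None, None] * J[..., None, None] * FinvT

    Fp = np.broadcast_to(F, (9,) + F.shape).astype(complex)
    pert = np.zeros((9, 3, 3), dtype=complex)
    pert[np.arange(9), np.arange(9) // 3, np.arange(9) % 3] = 1j * h
    Fp = Fp + pert.reshape((9,) + (1,) * (F.ndim - 2) + (3, 3))
    P = local_P(Fp).imag / h
    return np.moveaxis(P, 0, -1).reshape(F.shape + (3, 3))


def cauchy_stress(model: ConstitutiveModel, p) -> np.ndarray:
    """Cauchy stress sigma = P F^T / J (kPa), symmetric."""
    F = p.F if isinstance(p, DeformationPoint) else np.asarray(p)
    P = pk1_stress(model, F)
    J = det3(F)
    sig = (P @ np.swapaxes(F, -1, -2)) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))  # kill round-off asymmetry


def pk1_local_tangent_analytic(model: ConstitutiveModel, F,
                               pressure) -> np.ndarray:
    """Closed-form d/dF of [P_iso(F) + p J F^-T] at frozen pressure p.

    Algebraically identical to :func:`pk1_local_tangent` (which is kept as
    the independent complex-step oracle) but several times faster; used by
    the assembly hot path.
    """
    F = np.asarray(F, dtype=float)
    p = np.asarray(pressure, dtype=float)
    J, B, I1b, I2b, FinvT = _invariants(F)
    a = J ** (-2.0 / 3.0)

    eye = np.eye(3)
    T1 = np.einsum("ik,JL->iJkL", eye, eye)
    T4 = np.einsum("...iL,...kJ->...iJkL", FinvT, FinvT)
    H1 = a[..., None, None] * F - (I1b / 3.0)[..., None, None] * FinvT
    dH1 = (a[..., None, None, None, None] * T1
           - (2.0 / 3.0) * np.einsum("...,...iJ,...kL->...iJkL", a, F, FinvT)
           - (2.0 / 3.0) * np.einsum("...iJ,...kL->...iJkL", FinvT, H1)
           + (I1b / 3.0)[..., None, None, None, None] * T4)

    if model.kind == "neo_hookean":
        A = 0.5 * model.mu * (2.0 * dH1)
    else:
        c = model.coefficients
        al, be = I1b - 3.0, I2b - 3.0
        W1 = c["C10"] + c["C11"] * be + 2.0 * c["C20"] * al
        W2 = c["C01"] + c["C11"] * al + 2.0 * c["C02"] * be
        BF = B @ F
        H2 = (I1b * a)[..., None, None] * F - (a ** 2)[..., None, None] * BF \
            - (2.0 * I2b / 3.0)[..., None, None] * FinvT
        dI1 = 2.0 * H1
        dI2 = 2.0 * H2
        dW1 = c["C11"] * dI2 + 2.0 * c["C20"] * dI1
        dW2 = c["C11"] * dI1 + 2.0 * c["C02"] * dI2
        C = np.swapaxes(F, -1, -2) @ F
        dBF = (np.einsum("ik,...LJ->...iJkL", eye, C)
               + np.einsum("...iL,...kJ->...iJkL", F, F)
               + np.einsum("...ik,JL->...iJkL", B, eye))
        dI1a = 2.0 * a[..., None, None] * H1 \
            - (2.0 / 3.0) * (I1b * a)[..., None, None] * FinvT
        dH2 = (np.einsum("...iJ,...kL->...iJkL", F, dI1a)
               + (I1b * a)[..., None, None, None, None] * T1
               + (4.0 / 3.0) * np.einsum("...,...iJ,...kL->...iJkL",
                                         a ** 2, BF, FinvT)
               - (a ** 2)[..., None, None, None, None] * dBF
               - (2.0 / 3.0) * np.einsum("...iJ,...kL->...iJkL", FinvT, dI2)
               + (2.0 * I2b / 3.0)[..., None, None, None, None] * T4)
        A = (np.einsum("...iJ,...kL->...iJkL", H1, dW1)
             + W1[..., None, None, None, None] * dH1) * 2.0 \
            + (np.einsum("...iJ,...kL->...iJkL", H2, dW2)
               + W2[..., None, None, None, None] * dH2) * 2.0

    A = A + (p * J)[..., None, None, None, None] * (
        np.einsum("...iJ,...kL->...iJkL", FinvT, FinvT) - T4)
    return A


def pk1_tangent(model: ConstitutiveModel, F, h: float = 1e-30) -> np.ndarray:
    """Consistent material tangent A_{iJkL} = dP_iJ / dF_kL by complex-step
    differentiation of the analytic P (exact to machine precision)."""
    F = np.asarray(F, dtype=float)
    Fp = np.broadcast_to(F, (9,) + F.shape).astype(complex)
    pert = np.zeros((9, 3, 3), dtype=complex)
    pert[np.arange(9), np.arange(9) // 3, np.arange(9) % 3] = 1j * h
    Fp = Fp + pert.reshape((9,) + (1,) * (F.ndim - 2) + (3, 3))
    P = pk1_stress(model, Fp).imag / h          # (9, ..., 3, 3)
    A = np.moveaxis(P, 0, -1)                   # (..., 3, 3, 9)
    return A.reshape(F.shape + (3, 3))
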