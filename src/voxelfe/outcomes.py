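"""Mechanical outcomes of a solved compression test.

The four primary outcomes reported for every model variant:

* stiffness (kN/mm): axial distal reaction / applied displacement,
* apparent modulus (MPa): reaction / (cross-sectional area x 1 % strain),
* average von Mises stress (MPa) over the bone elements,
* failure load (kN) by the Pistoia criterion -- the linearly scaled load
  at which 2 % of the bone tissue exceeds a critical energy-equivalent
  strain (7000 ue single-tissue / density-scaled; 3500 ue dual-tissue,
  halved because the cortical modulus is doubled), or equivalently a
  70 MPa energy-equivalent stress for the stress variant.

Dual-tissue models additionally report per-tissue average von Mises
stress and the minimum/maximum percentage of the axial load carried by
each tissue across transverse element layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fe_model import CORT, MIXED, TRAB, BCSpec, HexMesh, Model
from .fe_solver import FESolution

STRAIN_LIMIT_SINGLE = 7000e-6   # STM and E-BMD
STRAIN_LIMIT_DUAL = 3500e-6     # DTM (cortical E doubled -> limit halved)
STRESS_LIMIT = 70.0             # MPa, stress-variant criterion
TISSUE_FRACTION = 0.02

_TISSUE_NAMES = {CORT: "cortical", TRAB: "trabecular"}


@dataclass
class FailureCriterion:
    tissue_fraction: float = TISSUE_FRACTION
    strain_limit: float = STRAIN_LIMIT_SINGLE
    variant: str = "strain"          # strain | stress
    stress_limit: float = STRESS_LIMIT

    def validate(self) -> None:
        if not 0 < self.tissue_fraction < 1:
            raise ValueError("tissue_fraction must be in (0, 1)")
        if self.strain_limit <= 0 or self.stress_limit <= 0:
            raise ValueError("failure limits must be positive")
        if self.variant not in ("strain", "stress"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @classmethod
    def for_model(cls, model: Model | str, variant: str = "strain",
                  ) -> "FailureCriterion":
        limit = STRAIN_LIMIT_DUAL if Model(model) is Model.DTM \
            else STRAIN_LIMIT_SINGLE
        return cls(strain_limit=limit, variant=variant)


@dataclass
class ModelOutcomes:
    model: str
    stiffness: float                 # kN/mm
    apparent_modulus: float          # MPa
    avg_von_mises: float             # MPa
    failure_load: float              # kN
    per_tissue: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        out = {"model": self.model, "stiffness_kN_mm": self.stiffness,
               "apparent_modulus_MPa": self.apparent_modulus,
               "avg_vm_MPa": self.avg_von_mises,
               "failure_load_kN": self.failure_load}
        for tissue, vals in self.per_tissue.items():
            for k, v in vals.items():
                out[f"{tissue}_{k}"] = v
        return out


def stiffness(sol: FESolution, mesh: HexMesh, bc: BCSpec | None = None) -> float:
    """Axial distal reaction force / applied displacement, in kN/mm."""
    bc = bc or BCSpec()
    delta = bc.applied_displacement(mesh)
    if delta == 0:
        raise ValueError("zero applied displacement")
    return abs(sol.reaction_distal) / delta / 1000.0


def apparent_modulus(sol: FESolution, bc: BCSpec, csa: float) -> float:
    """Reaction / (cross-sectional area x applied strain), in MPa."""
    if not csa > 0:
        raise ValueError("cross-sectional area must be positive")
    return abs(sol.reaction_distal) / (csa * bc.applied_strain)


def average_von_mises(sol: FESolution, mesh: HexMesh,
                      subset: str | None = None) -> float:
    """Unweighted mean element von Mises stress over all bone or a tissue
    subset ('cortical'/'trabecular'); equal-volume voxels make this the
    volume-weighted mean automatically."""
    sel = _tissue_selector(mesh, subset)
    if sel.sum() == 0:
        raise ValueError(f"empty subset {subset!r}")
    return float(sol.von_mises[sel].mean())


def _tissue_selector(mesh: HexMesh, subset: str | None) -> np.ndarray:
    if subset is None or subset == "all":
        return np.ones(mesh.n_elements, dtype=bool)
    code = {"cortical": CORT, "trabecular": TRAB}[subset]
    if mesh.tissue_per_element is None:
        raise ValueError("mesh carries no tissue labels")
    return mesh.tissue_per_element == code


def failure_load(sol: FESolution, mesh: HexMesh, crit: FailureCriterion,
                 ) -> float:
    """Pistoia-style failure load in kN.

    Exploits linearity: the solved 1 % load is scaled by
    ``s* = limit / q`` where ``q`` is the k-th largest per-element
    criterion value and ``k = ceil(tissue_fraction x N)`` -- at scale
    ``s*`` exactly the prescribed tissue fraction reaches the limit.
    The criterion value is the energy-equivalent strain
    ``sqrt(2U/E)`` (strain variant) or energy-equivalent stress
    ``sqrt(2UE)`` (stress variant).
    """
    crit.validate()
    if crit.variant == "strain":
        v = sol.eeq_strain
        limit = crit.strain_limit
    else:
        v = np.sqrt(2.0 * sol.sed * mesh.E_per_element)
        limit = crit.stress_limit
    n = v.size
    k = max(1, math.ceil(crit.tissue_fraction * n))
    q = float(np.partition(v, n - k)[n - k])
    if q <= 0:
        raise ValueError("degenerate criterion field (no strained tissue)")
    scale = limit / q
    return scale * abs(sol.reaction_distal) / 1000.0


def load_sharing(sol: FESolution, mesh: HexMesh) -> dict[str, dict[str, float]]:
    """Per-tissue axial load share, min/max over transverse layers.

    The axial force through a layer is the sum of element axial stress
    sigma_zz times the element cross-section; its split between cortical
    and trabecular elements gives the percentage carried by each tissue.
    """
    if mesh.tissue_per_element is None:
        raise ValueError("load sharing requires tissue labels")
    area = mesh.edge_length ** 2
    z = mesh.elements[:, 2]
    szz = sol.element_stress[:, 2] * area
    layers = np.unique(z)
    shares: dict[int, list[float]] = {CORT: [], TRAB: []}
    for layer in layers:
        in_layer = z == layer
        total = szz[in_layer].sum()
        if total == 0:
            continue
        for code in (CORT, TRAB):
            part = szz[in_layer & (mesh.tissue_per_element == code)].sum()
            shares[code].append(100.0 * part / total)
    out: dict[str, dict[str, float]] = {}
    for code, name in _TISSUE_NAMES.items():
        vals = np.array(shares[code])
        out[name] = {"pct_load_min": float(vals.min()),
                     "pct_load_max": float(vals.max())}
    return out


def layer_forces(sol: FESolution, mesh: HexMesh) -> np.ndarray:
    """Total axial force (N) through each transverse element layer."""
    area = mesh.edge_length ** 2
    z = mesh.elements[:, 2]
    szz = sol.element_stress[:, 2] * area
    return np.array([szz[z == layer].sum() for layer in np.unique(z)])


def compute_outcomes(sol: FESolution, mesh: HexMesh, bc: BCSpec, csa: float,
                     crit: FailureCriterion | None = None) -> ModelOutcomes:
    """All primary outcomes (plus DTM load-sharing/per-tissue stresses)."""
    crit = crit or FailureCriterion.for_model(mesh.model)
    res = ModelOutcomes(
        model=mesh.model.value,
        stiffness=stiffness(sol, mesh, bc),
        apparent_modulus=apparent_modulus(sol, bc, csa),
        avg_von_mises=average_von_mises(sol, mesh),
        failure_load=failure_load(sol, mesh, crit),
    )
    if mesh.model is Model.DTM:
        res.per_tissue = load_sharing(sol, mesh)
        for code, name in _TISSUE_NAMES.items():
            res.per_tissue[name]["avg_vm_MPa"] = \
                average_von_mises(sol, mesh, name)
    return res
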