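"""Voxel hexahedral mesh construction, material assignment and boundary
conditions for the three micro-FE model variants.

Every included voxel becomes one 8-node brick element with isotropic
linear-elastic material (shared Poisson ratio 0.3).  The three variants
differ only in which voxels are included and what Young's modulus each
element receives:

* STM  -- all bone voxels, one user modulus (standard 10 GPa),
* DTM  -- all bone voxels, cortical 20 GPa / trabecular 17 GPa,
* E-BMD -- all voxels inside the periosteal contour whose density-scaled
  modulus ``E = 15004 (rho/1200)^1.7`` MPa exceeds a small floor.

Units are mm / N / MPa throughout, so reactions come out in N and
stiffness in N/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .volume import CORT, TRAB, DensityVolume, LabelVolume

# Element-local node numbering: standard trilinear hexahedron, counter-
# clockwise around the bottom (z=0) face then the top face.
_NODE_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=np.int64)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

MIXED = 3  # tissue code for unlabelled (E-BMD partial-volume) elements


class Model(str, Enum):
    STM = "STM"
    DTM = "DTM"
    EBMD = "EBMD"


# Reference moduli (MPa)
E_STM_DEFAULT = 10000.0
E_STM_MACNEIL = 6829.0           # alternative single-tissue calibration
E_CORT_DEFAULT = 20000.0
E_TRAB_DEFAULT = 17000.0
EBMD_COEFF = 15004.0             # MPa at the reference density
EBMD_RHO_REF = 1200.0            # mg HA/cm^3, fully mineralised bone
EBMD_EXPONENT = 1.7
POISSON_DEFAULT = 0.3


@dataclass
class HexMesh:
    """Active voxel elements of one model on a common node lattice."""

    elements: np.ndarray            # (nel, 3) voxel coordinates (x, y, z)
    node_ids: np.ndarray            # (nel, 8) global node indices
    n_nodes: int
    grid_shape: tuple[int, int, int]
    edge_length: float              # mm
    E_per_element: np.ndarray | None = None   # MPa
    tissue_per_element: np.ndarray | None = None  # CORT/TRAB/MIXED codes
    poisson: float = POISSON_DEFAULT
    model: Model = Model.STM

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_slices(self) -> int:
        return self.grid_shape[2]

    def node_coordinates(self) -> np.ndarray:
        """(n_nodes, 3) lattice coordinates of the used nodes, in node units."""
        return self._node_coords

    def validate(self) -> None:
        if self.E_per_element is not None and not (self.E_per_element > 0).all():
            raise ValueError("every retained element must have E > 0")


@dataclass
class BCSpec:
    """High-friction axial compression: the distal face (slice 0 side) is
    displaced axially by 1 % of the region length with in-plane motion
    suppressed; the proximal face is fully fixed."""

    applied_strain: float = 0.01

    def applied_displacement(self, mesh: HexMesh) -> float:
        """Displacement magnitude in mm: strain x axial extent."""
        return self.applied_strain * mesh.n_slices * mesh.edge_length


@dataclass
class ConstrainedSystem:
    mesh: HexMesh
    bc: BCSpec
    prescribed_dofs: np.ndarray     # global dof indices
    prescribed_values: np.ndarray   # mm
    distal_nodes: np.ndarray        # node indices on the loaded face
    proximal_nodes: np.ndarray


def ebmd_modulus(rho: np.ndarray | float) -> np.ndarray | float:
    """Density-modulus power law ``E = 15004 (rho/1200)^1.7`` MPa.

    Negative densities (reconstruction noise) are clamped to zero before
    evaluation.
    """
    rho = np.maximum(np.asarray(rho, dtype=float), 0.0)
    out = EBMD_COEFF * (rho / EBMD_RHO_REF) ** EBMD_EXPONENT
    return out if out.ndim else float(out)


def _connected_to_both_faces(mask: np.ndarray) -> np.ndarray:
    """Keep the components (26-connectivity) touching both end slices."""
    comp, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return mask
    distal = np.unique(comp[:, :, 0])
    proximal = np.unique(comp[:, :, -1])
    keep = np.intersect1d(distal, proximal)
    keep = keep[keep != 0]
    if keep.size == 0:
        raise ValueError("disconnected structure: no load path between "
                         "distal and proximal faces")
    return np.isin(comp, keep)


def _index_nodes(include: np.ndarray) -> tuple[np.ndarray, np.ndarray, int,
                                               np.ndarray]:
    """Element list and deterministic node numbering.

    Nodes are numbered lexicographically by (z, y, x) over the set of
    lattice nodes actually touched by an element.
    """
    ex, ey, ez = np.nonzero(include)
    elements = np.stack([ex, ey, ez], axis=1)
    nx, ny, nz = include.shape
    # Global lattice node key, ordered by (z, y, x).
    def key(x, y, z):
        return (z * (ny + 1) + y) * (nx + 1) + x
    corner_keys = np.empty((len(elements), 8), dtype=np.int64)
    for c, (dx, dy, dz) in enumerate(_NODE_OFFSETS):
        corner_keys[:, c] = key(ex + dx, ey + dy, ez + dz)
    used = np.unique(corner_keys)
    node_ids = np.searchsorted(used, corner_keys)
    # Recover lattice coordinates of each used node.
    zk, rem = np.divmod(used, (ny + 1) * (nx + 1))
    yk, xk = np.divmod(rem, nx + 1)
    coords = np.stack([xk, yk, zk], axis=1)
    return elements, node_ids, len(used), coords


def build_mesh(labels: LabelVolume | np.ndarray,
               model: Model | str = Model.STM,
               vol: DensityVolume | None = None,
               periosteal: np.ndarray | None = None,
               E_floor: float = 1.0) -> HexMesh:
    """Convert the included voxels of one model variant into a hex mesh.

    STM/DTM include the (labelled) bone voxels; E-BMD includes every voxel
    inside the periosteal contour whose power-law modulus exceeds
    ``E_floor`` (default 1 MPa) and needs ``vol``.  Components without a
    load path between the two end slices are removed.
    """
    model = Model(model)
    if model is Model.EBMD:
        if vol is None or periosteal is None:
            raise ValueError("E-BMD meshing needs the density volume and the "
                             "periosteal mask")
        E_field = ebmd_modulus(vol.data)
        include = periosteal & (E_field > E_floor)
        edge = vol.voxel_size
        grid_shape = vol.data.shape
        tissue_src = labels.labels if isinstance(labels, LabelVolume) else None
    else:
        if isinstance(labels, LabelVolume):
            include = labels.bone
            tissue_src = labels.labels
            edge = labels.voxel_size
        else:
            include = np.asarray(labels, dtype=bool)
            tissue_src = None
            if vol is None:
                raise ValueError("mask input needs vol for the voxel size")
            edge = vol.voxel_size
        grid_shape = include.shape
        E_field = None

    include = _connected_to_both_faces(include)
    elements, node_ids, n_nodes, coords = _index_nodes(include)
    mesh = HexMesh(elements=elements, node_ids=node_ids, n_nodes=n_nodes,
                   grid_shape=tuple(grid_shape), edge_length=float(edge),
                   model=model)
    mesh._node_coords = coords
    if tissue_src is not None:
        t = tissue_src[elements[:, 0], elements[:, 1], elements[:, 2]]
        tissue = np.where(t == CORT, CORT, np.where(t == TRAB, TRAB, MIXED))
        mesh.tissue_per_element = tissue.astype(np.uint8)
    if model is Model.EBMD:
        mesh.E_per_element = E_field[elements[:, 0], elements[:, 1],
                                     elements[:, 2]]
    return mesh


def assign_stm(mesh: HexMesh, E: float = E_STM_DEFAULT) -> HexMesh:
    """Single-tissue model: one modulus for every bone element."""
    if not E > 0:
        raise ValueError("E must be positive")
    mesh.E_per_element = np.full(mesh.n_elements, float(E))
    mesh.model = Model.STM
    return mesh


def assign_dtm(mesh: HexMesh, E_cort: float = E_CORT_DEFAULT,
               E_trab: float = E_TRAB_DEFAULT) -> HexMesh:
    """Dual-tissue model: cortical and trabecular moduli from the labels."""
    if not (E_cort > 0 and E_trab > 0):
        raise ValueError("moduli must be positive")
    if mesh.tissue_per_element is None:
        raise ValueError("DTM requires tissue labels on the mesh")
    t = mesh.tissue_per_element
    if np.any(t == MIXED):
        raise ValueError("DTM mesh contains unlabelled elements")
    mesh.E_per_element = np.where(t == CORT, float(E_cort), float(E_trab))
    mesh.model = Model.DTM
    return mesh


def export_mesh_tables(mesh: HexMesh):
    """Node and element tables (pandas DataFrames) for debugging/CSV export."""
    import pandas as pd
    coords = mesh.node_coordinates() * mesh.edge_length
    nodes = pd.DataFrame(coords, columns=["x_mm", "y_mm", "z_mm"])
    nodes.index.name = "node_id"
    elems = pd.DataFrame(mesh.node_ids,
                         columns=[f"n{i}" for i in range(8)])
    if mesh.E_per_element is not None:
        elems["E_MPa"] = mesh.E_per_element
    if mesh.tissue_per_element is not None:
        elems["tissue"] = mesh.tissue_per_element
    elems.index.name = "element_id"
    return nodes, elems


def element_field_volume(mesh: HexMesh, values: np.ndarray,
                         fill: float = 0.0) -> np.ndarray:
    """Scatter a per-element field back onto the source voxel grid (for
    export as NIfTI alongside the input volume)."""
    out = np.full(mesh.grid_shape, fill, dtype=np.float32)
    out[mesh.elements[:, 0], mesh.elements[:, 1], mesh.elements[:, 2]] = values
    return out


def apply_bc(mesh: HexMesh, bc: BCSpec | None = None) -> ConstrainedSystem:
    """Constrain the mesh for the high-friction 1 % compression test.

    Distal face (node plane z = 0): axial displacement into the volume of
    magnitude ``applied_displacement``, in-plane displacements zero.
    Proximal face (z = n_slices): fully fixed.
    """
    bc = bc or BCSpec()
    coords = mesh.node_coordinates()
    distal = np.flatnonzero(coords[:, 2] == 0)
    proximal = np.flatnonzero(coords[:, 2] == mesh.n_slices)
    if distal.size == 0 or proximal.size == 0:
        raise ValueError("mesh does not reach both loaded faces")
    delta = bc.applied_displacement(mesh)

    dofs = [proximal * 3, proximal * 3 + 1, proximal * 3 + 2,
            distal * 3, distal * 3 + 1, distal * 3 + 2]
    vals = [np.zeros(proximal.size)] * 3 + \
           [np.zeros(distal.size)] * 2 + [np.full(distal.size, delta)]
    prescribed = np.concatenate(dofs)
    values = np.concatenate(vals)
    order = np.argsort(prescribed)
    return ConstrainedSystem(mesh=mesh, bc=bc,
                             prescribed_dofs=prescribed[order],
                             prescribed_values=values[order],
                             distal_nodes=distal, proximal_nodes=proximal)
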