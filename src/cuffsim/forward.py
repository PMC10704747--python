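"""Quasi-static bioelectric forward problem and reciprocity leadfield.

The volume conductor is discretized by a cell-centered finite-volume scheme
on the voxel grid: one potential unknown per conducting voxel, face
conductances from the harmonic mean of the adjoining voxel conductivities
(the lowest-order finite-element equivalent for ∇·(σ∇V) = −I with
insulating outer boundaries).  Endoneurium is anisotropic — a diagonal
tensor with the longitudinal component along the nerve axis.

Voxels whose conductivity falls below ``insulator_cutoff`` (the cuff at
1e-7 S/m, and everything outside the saline cylinder) are treated as
perfect insulators and carry no unknown; this removes a ~1e7 conductance
contrast from the linear system at a relative modeling error below 1e-6.

The leadfield is assembled by reciprocity: injecting a balanced unit
current between contact m and a fixed reference contact and solving once
gives, at every candidate source voxel, the sensitivity of channel m to an
axial dipole there (the axial gradient of the reciprocal potential).  M
channels therefore cost M−1 solves instead of one solve per source.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from cuffsim.geometry import (
    LABEL_ELECTRODE,
    LABEL_ENDONEURIUM,
    LABEL_EPINEURIUM,
    LABEL_OUTSIDE,
    LABEL_PERINEURIUM,
    LABEL_SALINE,
    ElectrodeLayout,
    NerveVolume,
)


class ForwardError(ValueError):
    """Forward-problem configuration error."""


class CurrentConservationError(ForwardError):
    """Injected source pattern does not sum to zero."""


class SolverError(RuntimeError):
    """Iterative solver failed to reach the requested tolerance."""


@dataclasses.dataclass(frozen=True)
class ConductivityTable:
    """Material conductivities in S/m (defaults from human-nerve literature)."""

    endoneurium_longitudinal: float = 0.5710
    endoneurium_transverse: float = 0.0826
    perineurium: float = 0.0021
    epineurium: float = 0.0826
    saline: float = 2.0
    cuff: float = 1e-7

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if value <= 0:
                raise ForwardError(f"conductivity {name} must be positive")


def assign_conductivity(
    volume: NerveVolume, table: ConductivityTable | None = None
) -> np.ndarray:
    """Per-voxel diagonal conductivity tensors, shape ``(*grid, 3)`` in S/m.

    Components are (σx, σy, σz).  Endoneurium is anisotropic with the
    longitudinal value along z (the nerve axis); every other material is
    isotropic.  Voxels outside the saline cylinder get zero conductivity.
    """
    table = table or ConductivityTable()
    iso = {
        LABEL_SALINE: table.saline,
        LABEL_PERINEURIUM: table.perineurium,
        LABEL_EPINEURIUM: table.epineurium,
        LABEL_ELECTRODE: table.cuff,
        LABEL_OUTSIDE: 0.0,
    }
    labels = volume.label_grid
    known = set(iso) | {LABEL_ENDONEURIUM}
    present = set(np.unique(labels).tolist())
    if not present <= known:
        raise ForwardError(f"unknown label codes {sorted(present - known)}")
    sigma = np.zeros(labels.shape + (3,), dtype=np.float64)
    for code, value in iso.items():
        sigma[labels == code] = value
    endo = labels == LABEL_ENDONEURIUM
    sigma[endo] = (
        table.endoneurium_transverse,
        table.endoneurium_transverse,
        table.endoneurium_longitudinal,
    )
    return sigma


@dataclasses.dataclass
class PotentialField:
    """Node potentials over the voxel grid (V); NaN at insulating voxels."""

    phi: np.ndarray
    residual: float
    iterations: int
    source_description: str = ""


class VoxelForwardProblem:
    """Assembled finite-volume system for one volume + conductivity field.

    Builds the sparse SPD operator once; individual injections then reuse
    it, which is what makes the 55 reciprocal solves of a leadfield cheap.
    The potential gauge is fixed by pinning one saline voxel on the domain
    boundary to zero during the solve and re-gauging returned fields to
    zero mean over the boundary saline nodes.
    """

    def __init__(
        self,
        volume: NerveVolume,
        sigma: np.ndarray | None = None,
        table: ConductivityTable | None = None,
        insulator_cutoff: float = 1e-6,
        tolerance: float = 1e-8,
    ) -> None:
        if sigma is None:
            sigma = assign_conductivity(volume, table)
        self.volume = volume
        self.sigma = sigma
        self.tolerance = tolerance
        active = sigma.max(axis=-1) > insulator_cutoff
        self.active = active
        self.index = -np.ones(active.shape, dtype=np.int64)
        self.index[active] = np.arange(int(active.sum()))
        self.n_unknowns = int(active.sum())
        if self.n_unknowns == 0:
            raise ForwardError("no conducting voxels")
        self._assemble()
        self._boundary_nodes = self._find_boundary_saline()
        self._pin = int(self._boundary_nodes[0])
        self.last_iterations = 0

    def _assemble(self) -> None:
        dx, dy, dz = self.volume.voxel_pitch
        # S/m -> S/mm so that mm geometry gives conductances in siemens
        sig = self.sigma * 1e-3
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_unknowns)
        face_geom = {0: dx * dz / dy, 1: dy * dz / dx, 2: dx * dy / dz}
        for axis in (0, 1, 2):
            comp = {0: 1, 1: 0, 2: 2}[axis]  # grid axis 0 is y, 1 is x, 2 is z
            s = sig[..., comp]
            sa = s[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))]
            sb = s[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))]
            ia = self.index[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))]
            ib = self.index[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))]
            both = (ia >= 0) & (ib >= 0)
            ssum = sa + sb
            with np.errstate(divide="ignore", invalid="ignore"):
                harm = np.where(ssum > 0, 2.0 * sa * sb / np.where(ssum > 0, ssum, 1.0), 0.0)
            g = harm * face_geom[axis]
            gb = g[both]
            ia_b, ib_b = ia[both], ib[both]
            keep = gb > 0
            gb, ia_b, ib_b = gb[keep], ia_b[keep], ib_b[keep]
            rows.append(ia_b)
            cols.append(ib_b)
            vals.append(-gb)
            rows.append(ib_b)
            cols.append(ia_b)
            vals.append(-gb)
            np.add.at(diag, ia_b, gb)
            np.add.at(diag, ib_b, gb)
        n = self.n_unknowns
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        self.matrix = A
        self._diag = A.diagonal().copy()

    def _find_boundary_saline(self) -> np.ndarray:
        """Active saline voxels adjacent to the insulating outer boundary."""
        act = self.active
        interior = np.zeros_like(act)
        interior[1:-1, 1:-1, 1:-1] = (
            act[1:-1, 1:-1, 1:-1]
            & act[:-2, 1:-1, 1:-1] & act[2:, 1:-1, 1:-1]
            & act[1:-1, :-2, 1:-1] & act[1:-1, 2:, 1:-1]
            & act[1:-1, 1:-1, :-2] & act[1:-1, 1:-1, 2:]
        )
        boundary = act & ~interior & (self.volume.label_grid == LABEL_SALINE)
        nodes = self.index[boundary]
        if nodes.size == 0:  # tiny test grids may have no saline at all
            nodes = self.index[act & ~interior]
        if nodes.size == 0:
            nodes = np.array([0])
        return np.sort(nodes)

    def solve(self, b: np.ndarray, tolerance: float | None = None) -> np.ndarray:
        """Solve for node potentials given a net-zero current vector (A)."""
        tol = tolerance or self.tolerance
        bnorm = np.abs(b).sum()
        if bnorm == 0:
            return np.zeros_like(b)
        if abs(b.sum()) > 1e-9 * bnorm:
            raise CurrentConservationError("current not conserved: sum(I) != 0")
        # Pin one boundary node: zero its row/column, unit diagonal.
        A = self.matrix
        pin = self._pin
        b = b.copy()
        b[pin] = 0.0
        diag = self._diag
        inv_diag = 1.0 / diag

        def matvec(x):
            y = A @ x
            y[pin] = x[pin]
            return y

        def precond(x):
            return x * inv_diag

        n = self.n_unknowns
        op = sparse.linalg.LinearOperator((n, n), matvec=matvec)
        M = sparse.linalg.LinearOperator((n, n), matvec=precond)
        count = [0]

        def cb(_xk):
            count[0] += 1

        x, info = cg(op, b, rtol=tol, atol=0.0, maxiter=20 * n, M=M, callback=cb)
        self.last_iterations = count[0]
        resid = np.linalg.norm(matvec(x) - b) / np.linalg.norm(b)
        if info != 0:
            raise SolverError(f"CG did not converge: relative residual {resid:.2e}")
        # Gauge: zero mean over boundary saline nodes.
        x = x - x[self._boundary_nodes].mean()
        return x

    def potential_grid(self, x: np.ndarray) -> np.ndarray:
        phi = np.full(self.active.shape, np.nan)
        phi[self.active] = x
        return phi

    def node_for_position(self, pos_mm: tuple[float, float, float]) -> int:
        """Nearest active voxel to a physical position (snapping inward in y).

        Contacts sit on the cuff's inner face; the face voxel itself may be
        cuff material, so the snap walks toward the nerve center until it
        hits a conducting voxel.
        """
        xg, yg = self.volume.xy_coords()
        zg = self.volume.z_coords
        px, py, pz = pos_mm
        ix = int(np.argmin(np.abs(xg - px)))
        iy = int(np.argmin(np.abs(yg - py)))
        iz = int(np.argmin(np.abs(zg - pz)))
        step = -1 if yg[iy] > 0 else 1
        for _ in range(self.active.shape[0]):
            if self.active[iy, ix, iz]:
                return int(self.index[iy, ix, iz])
            iy += step
            if not 0 <= iy < self.active.shape[0]:
                break
        raise ForwardError(f"no conducting voxel near contact at {pos_mm}")


def solve_potential(
    problem: VoxelForwardProblem,
    sources: list[tuple[tuple[int, int, int], float]],
    tolerance: float | None = None,
) -> PotentialField:
    """Solve ∇·(σ∇V) = −I for a balanced set of point current sources.

    ``sources`` is a list of ((iy, ix, iz) voxel index, current in A)
    pairs; the currents must sum to zero.
    """
    if abs(sum(c for _, c in sources)) > 1e-12 * max(
        1e-300, sum(abs(c) for _, c in sources)
    ):
        raise CurrentConservationError("current not conserved: sum(I) != 0")
    b = np.zeros(problem.n_unknowns)
    for (iy, ix, iz), current in sources:
        node = problem.index[iy, ix, iz]
        if node < 0:
            raise ForwardError(f"source voxel ({iy},{ix},{iz}) is insulating")
        b[node] += current
    x = problem.solve(b, tolerance)
    r = problem.matrix @ x - b
    r[problem._pin] = 0.0  # gauge row
    return PotentialField(
        phi=problem.potential_grid(x),
        residual=float(np.linalg.norm(r) / max(np.linalg.norm(b), 1e-300)),
        iterations=problem.last_iterations,
        source_description=f"{len(sources)} point sources",
    )


# ---------------------------------------------------------------------------
# Leadfield
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Leadfield:
    """M x N map from axial dipole sources to contact voltages.

    Columns are ordered ``node * n_slabs + slab``: all axial positions of
    one cross-section source node are contiguous, which makes the source
    chain of a propagating nCAP a contiguous column block.  Units: volts
    per unit axial dipole moment (A·mm).
    """

    matrix: np.ndarray  # (M, N)
    layout: ElectrodeLayout
    node_fascicle: np.ndarray  # (n_nodes,) fascicle id per cross-section node
    node_iy: np.ndarray
    node_ix: np.ndarray
    slab_iz: np.ndarray  # (n_slabs,) grid z-indices of the axial slabs
    slab_z: np.ndarray  # (n_slabs,) mm
    referenced: bool = False

    @property
    def n_nodes(self) -> int:
        return self.node_fascicle.size

    @property
    def n_slabs(self) -> int:
        return self.slab_iz.size

    def nodes_of_fascicle(self, fascicle_id: int) -> np.ndarray:
        return np.flatnonzero(self.node_fascicle == fascicle_id)

    def chain_columns(self, node: int) -> np.ndarray:
        """Column indices of one node's axial chain, in slab order."""
        return node * self.n_slabs + np.arange(self.n_slabs)

    def with_montage(self) -> "Leadfield":
        if self.referenced:
            return self
        return dataclasses.replace(
            self,
            matrix=apply_tripolar_montage(self.matrix, self.layout),
            referenced=True,
        )


def apply_tripolar_montage(x: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Re-reference channels to the mean of the two outer contact rings.

    Works identically on a leadfield (rows = channels) and on recordings,
    and commutes with D = L·J because it is a fixed linear map on rows.
    """
    if layout.n_layers < 2:
        raise ForwardError("montage impossible: fewer than 2 contact layers")
    x = np.asarray(x)
    if x.shape[0] != layout.n_contacts:
        raise ForwardError(
            f"expected {layout.n_contacts} channel rows, got {x.shape[0]}"
        )
    ref = x[layout.outer_ring_channels].mean(axis=0, keepdims=True)
    return x - ref


def build_leadfield(
    problem: VoxelForwardProblem,
    layout: ElectrodeLayout | None = None,
    reference_contact: int = 0,
    tolerance: float | None = None,
    montage: bool = True,
    progress: bool = False,
) -> Leadfield:
    """Assemble the leadfield by reciprocity, one solve per contact.

    For each contact m (vs. the fixed reference contact) a balanced unit
    source/sink pair is injected and solved; the row for channel m is the
    axial central difference of the reciprocal potential at every
    endoneurium voxel.  Source columns cover all endoneurium voxels at all
    interior axial slabs.
    """
    volume = problem.volume
    layout = layout or volume.layout
    cs = volume.cross_section
    endo_iy, endo_ix = np.nonzero(cs.fascicle_ids > 0)
    if endo_iy.size == 0:
        raise ForwardError("no endoneurium source voxels")
    node_fasc = cs.fascicle_ids[endo_iy, endo_ix].astype(int)
    order = np.lexsort((endo_ix, endo_iy, node_fasc))
    endo_iy, endo_ix, node_fasc = endo_iy[order], endo_ix[order], node_fasc[order]
    nz = volume.shape[2]
    slab_iz = np.arange(1, nz - 1)
    slab_z = volume.z_coords[slab_iz]
    dz = volume.voxel_pitch[2]

    n_nodes = endo_iy.size
    n_slabs = slab_iz.size
    m = layout.n_contacts
    L = np.zeros((m, n_nodes * n_slabs))
    contact_nodes = [
        problem.node_for_position(tuple(p)) for p in layout.contact_positions
    ]
    ref_node = contact_nodes[reference_contact]
    lin_plus = problem.index[endo_iy[:, None], endo_ix[:, None], slab_iz[None, :] + 1]
    lin_minus = problem.index[endo_iy[:, None], endo_ix[:, None], slab_iz[None, :] - 1]
    if np.any(lin_plus < 0) or np.any(lin_minus < 0):
        raise ForwardError("source voxel outside the conducting domain")
    for c in range(m):
        if c == reference_contact:
            continue
        b = np.zeros(problem.n_unknowns)
        b[contact_nodes[c]] += 1.0
        b[ref_node] -= 1.0
        x = problem.solve(b, tolerance)
        # dphi/dz (V/mm) at each (node, slab): channel sensitivity to a
        # unit axial dipole (A*mm) by reciprocity.
        L[c] = ((x[lin_plus] - x[lin_minus]) / (2.0 * dz)).ravel()
        if progress:
            print(f"leadfield solve {c + 1}/{m}", flush=True)
    lf = Leadfield(
        matrix=L,
        layout=layout,
        node_fascicle=node_fasc,
        node_iy=endo_iy,
        node_ix=endo_ix,
        slab_iz=slab_iz,
        slab_z=slab_z,
        referenced=False,
    )
    return lf.with_montage() if montage else lf
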