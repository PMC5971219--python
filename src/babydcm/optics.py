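"""Continuous-wave photon transport and channel sensitivity functions.

Solves the diffusion approximation (div(kappa grad) - mua) phi = -q with a
Robin boundary condition phi + 2 A kappa n.grad(phi) = 0 by linear finite
elements on the labeled head mesh, and builds channel sensitivity functions
(photon measurement density functions, PMDFs) from products of forward and
adjoint fluence fields with Rytov normalization.  A closed-form
extrapolated-boundary semi-infinite solution serves as an independent check
of the solver on homogeneous slabs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import HeadMesh, OptodeArray, TISSUE_SCALP, TISSUE_CSF, TISSUE_BRAIN

__all__ = [
    "OpticalCoefficients",
    "default_coefficients",
    "FluenceField",
    "SensitivityMatrix",
    "FEMSystem",
    "assemble_system",
    "solve_fluence",
    "analytic_semi_infinite_fluence",
    "compute_sensitivity",
    "channel_sensitivity_matrix",
    "region_sensitivity",
    "nodes_in_sphere",
]

DIRECT_SOLVE_MAX_NODES = 50_000


@dataclass
class OpticalCoefficients:
    """Baseline absorption/scattering per tissue label and wavelength.

    ``table`` maps (tissue_label, wavelength_nm) -> (mua, mus) in 1/mm, with
    mus interpreted as the reduced scattering coefficient (the standard
    diffusion-approximation reading of the kappa = 1/(3(mua+mus)) formula).
    ``A_boundary`` is the refractive-index-mismatch term of the Robin
    condition (>= 1; ~2.82 for a tissue-air interface with n ~ 1.4).
    """

    table: dict
    A_boundary: float = 2.82

    def __post_init__(self):
        if self.A_boundary < 1:
            raise ValueError("A_boundary must be >= 1")
        for key, (mua, mus) in self.table.items():
            if mua <= 0 or mus <= 0:
                raise ValueError(f"non-positive optical coefficients for {key}")

    def mua(self, label: int, wavelength: float) -> float:
        return self._get(label, wavelength)[0]

    def mus(self, label: int, wavelength: float) -> float:
        return self._get(label, wavelength)[1]

    def kappa(self, label: int, wavelength: float) -> float:
        mua, mus = self._get(label, wavelength)
        return 1.0 / (3.0 * (mua + mus))

    def _get(self, label, wavelength):
        try:
            return self.table[(label, wavelength)]
        except KeyError:
            raise KeyError(
                f"no optical coefficients for tissue label {label} at {wavelength} nm"
            ) from None

    def wavelengths(self):
        return sorted({wl for (_, wl) in self.table})

    def to_frame(self):
        import pandas as pd

        rows = [
            (lab, wl, mua, mus) for (lab, wl), (mua, mus) in sorted(self.table.items())
        ]
        return pd.DataFrame(rows, columns=["tissue", "wavelength", "mua", "mus"])

    @classmethod
    def from_frame(cls, frame, A_boundary: float = 2.82) -> "OpticalCoefficients":
        table = {
            (int(r.tissue), float(r.wavelength)): (float(r.mua), float(r.mus))
            for r in frame.itertuples()
        }
        return cls(table, A_boundary)


def default_coefficients() -> OpticalCoefficients:
    """Replaceable literature-style defaults for neonatal head tissue at
    770/850 nm (1/mm); not measured values from any single study."""
    table = {
        (TISSUE_SCALP, 770.0): (0.017, 0.74),
        (TISSUE_SCALP, 850.0): (0.019, 0.64),
        (TISSUE_CSF, 770.0): (0.004, 0.30),
        (TISSUE_CSF, 850.0): (0.004, 0.30),
        (TISSUE_BRAIN, 770.0): (0.018, 0.55),
        (TISSUE_BRAIN, 850.0): (0.021, 0.50),
    }
    return OpticalCoefficients(table)


@dataclass
class FluenceField:
    """Nodal fluence rate from one (physical or adjoint) source."""

    node_values: np.ndarray
    source_descriptor: dict

    def __post_init__(self):
        self.node_values = np.asarray(self.node_values, dtype=float)
        if not np.all(np.isfinite(self.node_values)):
            raise ValueError("fluence field contains non-finite values")


@dataclass
class SensitivityMatrix:
    """Channel x node optical sensitivity S0 per wavelength (Rytov sense:
    d(-ln I)/d(mua) locally), plus the channel list it refers to."""

    wavelengths: list
    S0: np.ndarray  # (n_wavelengths, n_channels, n_nodes)
    channel_names: list

    def __post_init__(self):
        self.S0 = np.asarray(self.S0, dtype=float)
        if self.S0.shape[0] != len(self.wavelengths):
            raise ValueError("wavelength axis mismatch")
        if self.S0.shape[1] != len(self.channel_names):
            raise ValueError("channel axis mismatch")
        if not np.all(np.isfinite(self.S0)):
            raise ValueError("sensitivity matrix contains non-finite entries")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["wavelengths"] = np.asarray(self.wavelengths, float)
            for wl, mat in zip(self.wavelengths, self.S0):
                f.create_dataset(f"S0/{wl:g}nm", data=mat)
            f.create_dataset(
                "channels", data=np.array(self.channel_names, dtype="S")
            )

    @classmethod
    def from_hdf5(cls, path) -> "SensitivityMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            wavelengths = [float(w) for w in f.attrs["wavelengths"]]
            S0 = np.stack([f[f"S0/{wl:g}nm"][()] for wl in wavelengths])
            channels = [c.decode() for c in f["channels"][()]]
        return cls(wavelengths, S0, channels)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class FEMSystem:
    """Assembled sparse Galerkin system for one wavelength."""

    matrix: sp.csr_matrix
    mesh: HeadMesh
    coeffs: OpticalCoefficients
    wavelength: float
    _factor: object = field(default=None, repr=False)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        n = self.matrix.shape[0]
        if n <= DIRECT_SOLVE_MAX_NODES:
            if self._factor is None:
                self._factor = spla.splu(self.matrix.tocsc())
            return self._factor.solve(rhs)
        x, info = spla.cg(self.matrix, rhs, rtol=1e-10, maxiter=5000)
        if info != 0:
            res = np.linalg.norm(self.matrix @ x - rhs) / np.linalg.norm(rhs)
            raise RuntimeError(f"CG did not converge (info={info}, residual={res:.3e})")
        return x


def _element_geometry(mesh: HeadMesh):
    """Per-element shape-function gradients and volumes for P1 tets."""
    p = mesh.nodes[mesh.elements]  # (M, 4, 3)
    J = p[:, 1:] - p[:, :1]  # (M, 3, 3) rows are edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    invJ = np.linalg.inv(J)  # (M, 3, 3)
    # gradients of barycentric shape functions
    g = np.empty((mesh.n_elements, 4, 3))
    g[:, 1:] = np.transpose(invJ, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def assemble_system(
    mesh: HeadMesh, coeffs: OpticalCoefficients, wavelength: float
) -> FEMSystem:
    """Linear-tetrahedron Galerkin assembly of the diffusion operator.

    Volume terms: integral(kappa grad(psi_i).grad(psi_j)) and
    integral(mua psi_i psi_j); boundary term integral(psi_i psi_j / (2A))
    over the whole boundary (the Robin condition).  The result is symmetric
    positive definite.
    """
    labels = np.unique(mesh.element_label)
    kappa_by_label = {int(l): coeffs.kappa(int(l), wavelength) for l in labels}
    mua_by_label = {int(l): coeffs.mua(int(l), wavelength) for l in labels}

    grads, vol = _element_geometry(mesh)
    kappa_e = np.vectorize(kappa_by_label.get)(mesh.element_label)
    mua_e = np.vectorize(mua_by_label.get)(mesh.element_label)

    # stiffness: K_ij = kappa * V * grad_i . grad_j
    Ke = np.einsum("eik,ejk->eij", grads, grads) * (kappa_e * vol)[:, None, None]
    # consistent mass: M_ij = mua * V/20 * (1 + delta_ij)
    mass_pattern = (np.ones((4, 4)) + np.eye(4)) / 20.0
    Me = mass_pattern[None] * (mua_e * vol)[:, None, None]
    Ae = Ke + Me

    rows = np.repeat(mesh.elements, 4, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 4)).ravel()
    A = sp.coo_matrix(
        (Ae.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()

    # Robin boundary: surface mass with coefficient 1/(2A_boundary)
    f = mesh.boundary_faces
    p = mesh.nodes[f]
    area = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    tri_pattern = (np.ones((3, 3)) + np.eye(3)) / 12.0
    Be = tri_pattern[None] * (area / (2.0 * coeffs.A_boundary))[:, None, None]
    rows_b = np.repeat(f, 3, axis=1).ravel()
    cols_b = np.tile(f, (1, 3)).ravel()
    B = sp.coo_matrix(
        (Be.ravel(), (rows_b, cols_b)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()

    return FEMSystem((A + B).tocsr(), mesh, coeffs, wavelength)


# ---------------------------------------------------------------------------
# Source placement and solves
# ---------------------------------------------------------------------------


def _locate_element(mesh: HeadMesh, point: np.ndarray):
    """Containing element and barycentric weights for an interior point."""
    from scipy.spatial import cKDTree

    if not hasattr(mesh, "_centroid_tree"):
        centroids = mesh.nodes[mesh.elements].mean(axis=1)
        mesh._centroid_tree = cKDTree(centroids)
        mesh._geom_cache = _element_geometry(mesh)
    tree = mesh._centroid_tree
    k = min(64, mesh.n_elements)
    _, cand = tree.query(point, k=k)
    cand = np.atleast_1d(cand)
    p = mesh.nodes[mesh.elements[cand]]
    # barycentric coordinates of the point in each candidate element
    T = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))
    lam = np.linalg.solve(T, (point - p[:, 0])[..., None])[..., 0]
    bary = np.concatenate([1 - lam.sum(axis=1, keepdims=True), lam], axis=1)
    ok = np.all(bary > -1e-9, axis=1)
    if not np.any(ok):
        raise ValueError(f"point {point} lies outside the mesh")
    e = cand[np.argmax(ok)]
    w = np.clip(bary[np.argmax(ok)], 0.0, None)
    return int(e), w / w.sum()


def _buried_point_load(system: FEMSystem, entry_point) -> tuple:
    """Load vector for a collimated optode: isotropic point source one
    reduced scattering length below the boundary entry point."""
    from .mesh import project_to_scalp

    mesh = system.mesh
    entry = project_to_scalp(np.asarray(entry_point, float), mesh)
    if np.linalg.norm(entry - np.asarray(entry_point, float)) > 1e-6 + 1e-3 * np.abs(
        np.asarray(entry_point)
    ).max():
        pass  # optode given off-surface; projected silently
    # inward direction: use face normal of nearest boundary face
    mus = system.coeffs.mus(TISSUE_SCALP, system.wavelength)
    depth = 1.0 / mus
    # slab scalp face is z = min z; general inward normal from boundary face
    normal = _inward_normal(mesh, entry)
    src = entry + depth * normal
    e, w = _locate_element(mesh, src)
    load = np.zeros(mesh.n_nodes)
    load[mesh.elements[e]] = w
    return load, src


def _inward_normal(mesh: HeadMesh, point_on_boundary):
    tri = mesh.nodes[mesh.boundary_faces]
    cent = tri.mean(axis=1)
    d2 = np.einsum("ij,ij->i", cent - point_on_boundary, cent - point_on_boundary)
    fi = int(np.argmin(d2))
    a, b, c = tri[fi]
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    # boundary faces are outward-oriented (opposite-vertex convention);
    # verify against the mesh interior and flip if needed
    interior = mesh.nodes.mean(axis=0)
    if np.dot(n, interior - a) > 0:
        n = -n
    return -n  # inward


def solve_fluence(system: FEMSystem, source_position, source_power: float = 1.0) -> FluenceField:
    """Fluence field for a physical or adjoint source at a boundary optode."""
    load, buried = _buried_point_load(system, source_position)
    phi = system.solve(source_power * load)
    return FluenceField(
        phi,
        {
            "position": np.asarray(source_position, float),
            "buried_position": buried,
            "power": source_power,
        },
    )


def analytic_semi_infinite_fluence(rho, z, mua, mus, A_boundary=2.82):
    """Extrapolated-boundary closed form for a semi-infinite homogeneous
    medium: real isotropic source at depth z0 = 1/mus, negative image
    mirrored about the extrapolated plane z = -zb, zb = 2 A kappa.

    phi = 1/(4 pi kappa) [exp(-mueff r1)/r1 - exp(-mueff r2)/r2]
    """
    if mua <= 0 or mus <= 0:
        raise ValueError("optical coefficients must be positive")
    kappa = 1.0 / (3.0 * (mua + mus))
    mueff = np.sqrt(mua / kappa)
    z0 = 1.0 / mus
    zb = 2.0 * A_boundary * kappa
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    r1 = np.sqrt(rho**2 + (z - z0) ** 2)
    r2 = np.sqrt(rho**2 + (z + z0 + 2 * zb) ** 2)
    if np.any(r1 == 0):
        raise ValueError("evaluation at the source point (r1 = 0)")
    return (np.exp(-mueff * r1) / r1 - np.exp(-mueff * r2) / r2) / (4 * np.pi * kappa)


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------


def nodal_volumes(mesh: HeadMesh) -> np.ndarray:
    """Lumped-mass nodal volume shares (each tet contributes V/4 per node)."""
    vol = mesh.element_volumes()
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.elements.ravel(), np.repeat(vol / 4.0, 4))
    return out


def compute_sensitivity(
    forward: FluenceField,
    adjoint: FluenceField,
    measurement_amplitude: float,
    mesh: HeadMesh,
) -> np.ndarray:
    """Per-node PMDF row: phi_fwd * phi_adj weighted by nodal volume share,
    normalized by the unperturbed measurement amplitude (Rytov), so each
    entry approximates d(-ln I)/d(mua) for a local absorption change."""
    if measurement_amplitude <= 0:
        raise ValueError("measurement_amplitude must be positive")
    if forward.node_values.shape != adjoint.node_values.shape:
        raise ValueError("forward and adjoint fields are not on the same mesh")
    vols = nodal_volumes(mesh)
    return forward.node_values * adjoint.node_values * vols / measurement_amplitude


def measurement_amplitude(system: FEMSystem, fluence: FluenceField, detector_position) -> float:
    """Detected amplitude: the fluence interpolated at the detector's buried
    point (same weights as the adjoint load, preserving exact reciprocity)."""
    load, _ = _buried_point_load(system, detector_position)
    return float(load @ fluence.node_values)


def channel_sensitivity_matrix(
    mesh: HeadMesh,
    array: OptodeArray,
    coeffs: OpticalCoefficients,
    wavelengths=None,
) -> SensitivityMatrix:
    """Assemble PMDF rows for every channel and wavelength.

    One forward solve per source and one adjoint solve per detector
    (4 + 4 for the fixture), reused across the 9 channels.
    """
    if wavelengths is None:
        wavelengths = coeffs.wavelengths()
    all_mats = []
    for wl in wavelengths:
        system = assemble_system(mesh, coeffs, wl)
        fwd = {s: solve_fluence(system, pos) for s, pos in array.sources.items()}
        adj = {d: solve_fluence(system, pos) for d, pos in array.detectors.items()}
        rows = []
        for s, d in array.channels:
            amp = measurement_amplitude(system, fwd[s], array.detectors[d])
            rows.append(compute_sensitivity(fwd[s], adj[d], amp, mesh))
        all_mats.append(np.array(rows))
    return SensitivityMatrix(list(wavelengths), np.stack(all_mats), array.channel_names())


def nodes_in_sphere(mesh: HeadMesh, centre, radius: float, label=TISSUE_BRAIN) -> np.ndarray:
    """Node indices within ``radius`` mm of ``centre`` that belong to at
    least one element of the given tissue label."""
    centre = np.asarray(centre, float)
    d = np.linalg.norm(mesh.nodes - centre, axis=1)
    near = d <= radius
    tagged = np.zeros(mesh.n_nodes, dtype=bool)
    tagged[np.unique(mesh.elements[mesh.element_label == label])] = True
    return np.nonzero(near & tagged)[0]


def region_sensitivity(S: SensitivityMatrix, regions: dict):
    """Condense node sensitivities into a channels x regions table per
    wavelength by summing S0 entries over each region's node set.

    Returns an (n_wavelengths, n_channels, n_regions) array plus the region
    name order.
    """
    names = list(regions)
    for name in names:
        if len(np.asarray(regions[name])) == 0:
            raise ValueError(f"region {name!r} has an empty node set")
    out = np.stack(
        [
            np.stack([S.S0[w][:, np.asarray(regions[n], int)].sum(axis=1) for n in names], axis=1)
            for w in range(len(S.wavelengths))
        ]
    )
    return out, names
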