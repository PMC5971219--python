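"""Synthetic layered head geometry and the optode probe fixture.

The study geometry is a three-layer infant head (scalp/skull + extra-cerebral
tissue, CSF, brain) carrying a 4-source / 4-detector array with nine channels
at 2 cm separation.  Here the head is a structured tetrahedral slab -- flat
scalp at z = 0, depth increasing with +z -- which keeps an analytic photon
oracle available while preserving the layered optics of the real anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TISSUE_SCALP = 1
TISSUE_CSF = 2
TISSUE_BRAIN = 3

__all__ = [
    "HeadMesh",
    "OptodeArray",
    "build_layered_slab_mesh",
    "build_fixture_array",
    "channel_midpoint",
    "project_to_scalp",
]


@dataclass
class HeadMesh:
    """Labeled tetrahedral volume mesh.

    Attributes
    ----------
    nodes : (N, 3) float array, coordinates in mm.
    elements : (M, 4) int array of node indices, positively oriented.
    element_label : (M,) int array with values in {1, 2, 3}
        (1 scalp/skull/extra-cerebral, 2 CSF, 3 brain).
    boundary_faces : (F, 3) int array of triangles on the domain boundary.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_label: np.ndarray
    boundary_faces: np.ndarray = field(default=None)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_label = np.asarray(self.element_label, dtype=np.int64)
        if self.boundary_faces is None:
            self.boundary_faces = extract_boundary_faces(self.elements)
        else:
            self.boundary_faces = np.asarray(self.boundary_faces, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_volumes(self) -> np.ndarray:
        """Signed volumes of all tetrahedra (positive for valid meshes)."""
        p = self.nodes[self.elements]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise ValueError("element refers to a node index out of range")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise ValueError("mesh contains non-positively-oriented tetrahedra")
        bad = set(np.unique(self.element_label)) - {TISSUE_SCALP, TISSUE_CSF, TISSUE_BRAIN}
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        # closed surface: every boundary edge shared by exactly two boundary faces
        f = self.boundary_faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("boundary is not a closed surface")

    # --- I/O -------------------------------------------------------------

    def save_ascii(self, path) -> None:
        """Write the ASCII node/element format:
        node lines ``id x y z`` then element lines ``id n1 n2 n3 n4 label``."""
        with open(path, "w") as fh:
            fh.write(f"# nodes {self.n_nodes}\n")
            for i, (x, y, z) in enumerate(self.nodes):
                fh.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
            fh.write(f"# elements {self.n_elements}\n")
            for i, (el, lab) in enumerate(zip(self.elements, self.element_label)):
                fh.write(f"{i} {el[0]} {el[1]} {el[2]} {el[3]} {lab}\n")

    @classmethod
    def load_ascii(cls, path) -> "HeadMesh":
        nodes, elems, labels = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) == 4:
                    nodes.append([float(v) for v in parts[1:]])
                elif len(parts) == 6:
                    elems.append([int(v) for v in parts[1:5]])
                    labels.append(int(parts[5]))
                else:
                    raise ValueError(f"unparseable mesh line: {line!r}")
        return cls(np.array(nodes), np.array(elems), np.array(labels))

    def save_gmsh(self, path) -> None:
        """Export to Gmsh 2.2 ASCII (a standard mesh interchange format)."""
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
            fh.write(f"$Nodes\n{self.n_nodes}\n")
            for i, (x, y, z) in enumerate(self.nodes, start=1):
                fh.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
            fh.write(f"$EndNodes\n$Elements\n{self.n_elements}\n")
            for i, (el, lab) in enumerate(zip(self.elements + 1, self.element_label), start=1):
                fh.write(f"{i} 4 2 {lab} {lab} {el[0]} {el[1]} {el[2]} {el[3]}\n")
            fh.write("$EndElements\n")


def extract_boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Faces that belong to exactly one tetrahedron."""
    faces = np.concatenate(
        [
            elements[:, [1, 2, 3]],
            elements[:, [0, 3, 2]],
            elements[:, [0, 1, 3]],
            elements[:, [0, 2, 1]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


# Kuhn subdivision of the unit cube into six tetrahedra sharing the main
# diagonal (0,0,0)-(1,1,1); identical in every cell, hence conforming.
_KUHN_PATHS = [
    (0, 1, 2),
    (0, 2, 1),
    (1, 0, 2),
    (1, 2, 0),
    (2, 0, 1),
    (2, 1, 0),
]


def build_layered_slab_mesh(
    extent_xyz,
    layer_thicknesses,
    target_edge_length: float,
    origin=(0.0, 0.0, 0.0),
) -> HeadMesh:
    """Structured tetrahedral slab with depth-based tissue labels.

    Parameters
    ----------
    extent_xyz : (ex, ey, ez) box dimensions in mm.
    layer_thicknesses : three positive thicknesses (scalp/skull, CSF, brain)
        in mm, summing to ``ez``; labels are assigned by element-centroid
        depth below the scalp face at z = origin_z.
    target_edge_length : requested grid spacing in mm (the actual spacing
        divides each extent evenly and never exceeds the target).
    origin : coordinates of the scalp-face corner, mm.
    """
    extent = np.asarray(extent_xyz, dtype=float)
    thick = np.asarray(layer_thicknesses, dtype=float)
    if np.any(extent <= 0):
        raise ValueError(f"extent_xyz must be positive, got {extent_xyz}")
    if thick.shape != (3,) or np.any(thick <= 0):
        raise ValueError(f"layer_thicknesses needs three positive values, got {layer_thicknesses}")
    if abs(thick.sum() - extent[2]) > 1e-9:
        raise ValueError(
            f"layer_thicknesses sum to {thick.sum()} but extent z is {extent[2]}"
        )
    if target_edge_length <= 0:
        raise ValueError(f"target_edge_length must be positive, got {target_edge_length}")

    ncell = np.maximum(1, np.ceil(extent / target_edge_length - 1e-12).astype(int))
    nx, ny, nz = ncell + 1

    xs = origin[0] + np.linspace(0, extent[0], nx)
    ys = origin[1] + np.linspace(0, extent[1], ny)
    zs = origin[2] + np.linspace(0, extent[2], nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ii, jj, kk = np.meshgrid(
        np.arange(ncell[0]), np.arange(ncell[1]), np.arange(ncell[2]), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    corner = np.stack([ii, jj, kk], axis=1)  # (C, 3)

    elems = []
    for path in _KUHN_PATHS:
        steps = np.zeros((4, 3), dtype=int)
        for s, axis in enumerate(path):
            steps[s + 1] = steps[s]
            steps[s + 1, axis] += 1
        verts = corner[:, None, :] + steps[None, :, :]  # (C, 4, 3)
        idx = nid(verts[..., 0], verts[..., 1], verts[..., 2])
        elems.append(idx)
    elements = np.concatenate(elems)

    # enforce positive orientation
    p = nodes[elements]
    vol6 = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    flip = vol6 < 0
    elements[flip] = elements[flip][:, [0, 2, 1, 3]]

    centroids_z = nodes[elements][:, :, 2].mean(axis=1)
    depth = centroids_z - origin[2]
    bounds = np.cumsum(thick)
    label = np.full(elements.shape[0], TISSUE_BRAIN, dtype=np.int64)
    label[depth < bounds[1]] = TISSUE_CSF
    label[depth < bounds[0]] = TISSUE_SCALP

    mesh = HeadMesh(nodes, elements, label)
    return mesh


# ---------------------------------------------------------------------------
# Optode array
# ---------------------------------------------------------------------------


@dataclass
class OptodeArray:
    """Source/detector positions and the channel (pairing) list.

    ``sources`` and ``detectors`` map id -> 3-D position (mm); ``channels``
    is an ordered list of (source_id, detector_id) pairs, all at
    ``nominal_separation`` mm for the study fixture.
    """

    sources: dict
    detectors: dict
    channels: list
    nominal_separation: float = 20.0

    def __post_init__(self):
        self.sources = {k: np.asarray(v, dtype=float) for k, v in self.sources.items()}
        self.detectors = {k: np.asarray(v, dtype=float) for k, v in self.detectors.items()}
        for s, d in self.channels:
            if s not in self.sources:
                raise ValueError(f"channel references unknown source {s!r}")
            if d not in self.detectors:
                raise ValueError(f"channel references unknown detector {d!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_names(self) -> list:
        return [f"{s}-{d}" for s, d in self.channels]

    def separation(self, channel) -> float:
        s, d = self._resolve(channel)
        return float(np.linalg.norm(self.sources[s] - self.detectors[d]))

    def _resolve(self, channel):
        if isinstance(channel, int):
            if not 0 <= channel < len(self.channels):
                raise KeyError(f"channel index {channel} out of range")
            return self.channels[channel]
        if isinstance(channel, str) and "-" in channel:
            s, d = channel.split("-", 1)
            if (s, d) in self.channels:
                return (s, d)
        if tuple(channel) in self.channels:
            return tuple(channel)
        raise KeyError(f"unknown channel {channel!r}")

    def to_frame(self):
        import pandas as pd

        rows = [("source", k, *v) for k, v in self.sources.items()]
        rows += [("detector", k, *v) for k, v in self.detectors.items()]
        return pd.DataFrame(rows, columns=["role", "id", "x", "y", "z"])

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame, nominal_separation: float = 20.0) -> "OptodeArray":
        sources = {
            str(r.id): (r.x, r.y, r.z) for r in frame.itertuples() if r.role == "source"
        }
        detectors = {
            str(r.id): (r.x, r.y, r.z) for r in frame.itertuples() if r.role == "detector"
        }
        channels = _pair_channels(sources, detectors, nominal_separation)
        return cls(sources, detectors, channels, nominal_separation)


def _pair_channels(sources, detectors, separation, tol=1e-9):
    """All source-detector pairs at the nominal separation, ordered by
    detector id then source id (insertion-order independent)."""
    channels = []
    for d in sorted(detectors):
        for s in sorted(sources):
            dist = np.linalg.norm(np.asarray(sources[s], float) - np.asarray(detectors[d], float))
            if abs(dist - separation) <= tol:
                channels.append((s, d))
    return channels


_FIXTURE_SOURCES = {
    "S1": (0.0, 0.0, 0.0),
    "S2": (40.0, 0.0, 0.0),
    "S3": (20.0, 20.0, 0.0),
    "S4": (20.0, -20.0, 0.0),
}
_FIXTURE_DETECTORS = {
    "D1": (20.0, 0.0, 0.0),
    "D2": (0.0, 20.0, 0.0),
    "D3": (40.0, 20.0, 0.0),
    "D4": (-20.0, 0.0, 0.0),
}


def build_fixture_array() -> OptodeArray:
    """The probe fixture: 4 sources + 4 detectors on the scalp plane giving
    exactly nine channels at 20 mm separation (the study's array topology;
    the planar coordinates are the package's own reconstruction)."""
    channels = _pair_channels(_FIXTURE_SOURCES, _FIXTURE_DETECTORS, 20.0)
    return OptodeArray(dict(_FIXTURE_SOURCES), dict(_FIXTURE_DETECTORS), channels, 20.0)


def channel_midpoint(array: OptodeArray, channel) -> np.ndarray:
    """Arithmetic midpoint of a channel's source and detector positions --
    the fiducial centre used to localize the channel on the scalp."""
    s, d = array._resolve(channel)
    return 0.5 * (array.sources[s] + array.detectors[d])


def project_to_scalp(point, mesh: HeadMesh) -> np.ndarray:
    """Closest point on the mesh boundary surface to ``point``.

    Exact point-to-triangle projection minimized over all boundary faces;
    ties resolve to the lowest face index.
    """
    if mesh.boundary_faces is None or len(mesh.boundary_faces) == 0:
        raise ValueError("mesh has no boundary faces")
    p = np.asarray(point, dtype=float)
    tri = mesh.nodes[mesh.boundary_faces]  # (F, 3, 3)
    proj = _closest_point_on_triangles(p, tri)
    d2 = np.einsum("ij,ij->i", proj - p, proj - p)
    return proj[int(np.argmin(d2))]


def _closest_point_on_triangles(p, tri):
    """Vectorized closest point on each triangle (Ericson's algorithm)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out
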