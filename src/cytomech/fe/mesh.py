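"""Tetrahedral meshing of an adherent cell and embedded basal filaments.

The cell is a half-ellipsoid sitting on a flat base (the adhesion plane
z = 0) with an embedded ellipsoidal nucleus.  The volume is meshed with
linear 4-node tetrahedra built from a jittered lattice plus surface points
via Delaunay triangulation in a unit half-ball reference space, then
anisotropically scaled to the physical semi-axes.  The membrane is the
single layer of elements owning a face on the curved apical surface; the
base nodes (z = 0) are the fixed set.

Actin stress fibers are modelled as straight truss chains embedded in the
continuum just above the adhesion plane: each truss segment's endpoints are
located inside host tetrahedra and coupled to the host nodes by barycentric
interpolation, so the fiber direction is exact regardless of the mesh.

Coordinates are micrometres; the cell long axis is +x; the filament angle
alpha is measured in the basal plane from +x.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay


class MeshError(ValueError):
    """Invalid or degenerate mesh geometry."""


REGIONS = ("cytoplasm", "nucleus")


@dataclass
class EmbeddedTruss:
    """One axial (truss) segment embedded in the tet mesh.

    Endpoint displacements follow the host tetrahedra through barycentric
    weights; ``EA`` is the axial rigidity in Pa*um^2.
    """

    tet_a: int
    bary_a: np.ndarray  # (4,)
    tet_b: int
    bary_b: np.ndarray  # (4,)
    direction: np.ndarray  # (3,) unit vector
    length: float  # um
    EA: float  # Pa * um^2


@dataclass
class CellMesh:
    """Tetrahedral cell discretisation with region labels and feature sets."""

    nodes: np.ndarray  # (n, 3) um
    tets: np.ndarray  # (m, 4) int
    region: np.ndarray  # (m,) int index into REGIONS
    membrane_faces: np.ndarray  # (k, 3) node triples on the apical surface
    membrane_owner: np.ndarray  # (k,) owning tet of each apical face
    base_nodes: np.ndarray  # (b,) node ids at z = 0
    filaments: list[EmbeddedTruss] = field(default_factory=list)
    cell_semi_axes: tuple[float, float, float] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def membrane_elements(self) -> np.ndarray:
        """Tet indices forming the apical membrane layer."""
        return np.unique(self.membrane_owner)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0
        return v

    def max_edge_length(self) -> float:
        p = self.nodes[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return max(
            float(np.linalg.norm(p[:, i] - p[:, j], axis=1).max()) for i, j in pairs
        )

    def face_areas(self, faces: np.ndarray) -> np.ndarray:
        p = self.nodes[faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )


def _boundary_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Faces appearing in exactly one tet, with their owner tet index."""
    combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = np.concatenate([tets[:, c] for c in combos])
    owners = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    solo = counts[inv] == 1
    return faces[solo], owners[solo]


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    v = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = np.where(v < 0)[0]
    tets = tets.copy()
    tets[flip, 0], tets[flip, 1] = tets[flip, 1].copy(), tets[flip, 0].copy()
    return tets


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Roughly uniform points on the open upper unit hemisphere."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1)
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_cell_mesh(
    cell_semi_axes: tuple[float, float, float] = (20.0, 10.0, 8.0),
    nucleus_semi_axes: tuple[float, float, float] = (6.0, 4.0, 2.0),
    nucleus_center: tuple[float, float, float] = (0.0, 0.0, 3.5),
    target_elements: int = 5000,
    seed: int = 0,
) -> CellMesh:
    """Mesh a half-ellipsoid cell on a flat base with an embedded nucleus.

    Points are laid out in a unit half-ball reference space (interior
    lattice with deterministic jitter, Fibonacci points on the hemisphere,
    a ring on the base circle), triangulated with Delaunay, and scaled to
    the physical semi-axes.  Tets are labelled nucleus or cytoplasm by the
    fraction of fixed interior sample points falling inside the nucleus
    ellipsoid.

    Raises :class:`MeshError` if the nucleus does not fit strictly inside
    the cell or elements degenerate.
    """
    a, b, c = (float(v) for v in cell_semi_axes)
    an, bn, cn = (float(v) for v in nucleus_semi_axes)
    ncx, ncy, ncz = (float(v) for v in nucleus_center)
    if min(a, b, c, an, bn, cn) <= 0:
        raise MeshError("all semi-axes must be positive")
    if not (500 <= target_elements <= 50_000):
        raise MeshError("target_elements must lie in [500, 50000]")
    # nucleus strictly interior: sample its surface, require inside the cell
    th = np.linspace(0, math.pi, 24)
    ph = np.linspace(0, 2 * math.pi, 48)
    TH, PH = np.meshgrid(th, ph)
    sx = ncx + an * np.sin(TH) * np.cos(PH)
    sy = ncy + bn * np.sin(TH) * np.sin(PH)
    sz = ncz + cn * np.cos(TH)
    rho = (sx / a) ** 2 + (sy / b) ** 2 + (sz / c) ** 2
    if np.any(rho >= 1.0) or np.any(sz <= 0.0):
        raise MeshError("nucleus must lie strictly inside the cell half-ellipsoid")

    # reference-space spacing from the element budget (~6 tets per lattice cell)
    h = (6.0 * (2.0 * math.pi / 3.0) / target_elements) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)

    ax1d = np.arange(-1.0, 1.0 + h / 2, h)
    z1d = np.arange(0.0, 1.0 + h / 2, h)
    X, Y, Z = np.meshgrid(ax1d, ax1d, z1d, indexing="ij")
    lat = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.linalg.norm(lat, axis=1)
    lat = lat[r <= 1.0 - 0.35 * h]
    interior = lat[:, 2] > 1e-12
    jit = rng.uniform(-0.12 * h, 0.12 * h, size=lat.shape)
    jit[~interior, 2] = 0.0  # keep the base plane flat
    lat = lat + jit

    n_surf = max(30, int(round(2.0 * math.pi / h**2)))
    surf = _fibonacci_hemisphere(n_surf)
    surf = surf[surf[:, 2] > 0.25 * h]
    n_ring = max(12, int(round(2.0 * math.pi / h)))
    tr = 2.0 * math.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([np.cos(tr), np.sin(tr), np.zeros(n_ring)])

    pts = np.vstack([lat, surf, ring])
    tri = Delaunay(pts, qhull_options="QJ")
    tets = tri.simplices
    nodes = pts * np.array([a, b, c])

    # drop degenerate slivers, fix orientation
    p = nodes[tets]
    vol = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0
    keep = np.abs(vol) > 1e-8 * a * b * c * h**3
    tets = tets[keep]
    tets = _fix_orientation(nodes, tets)

    # drop orphan nodes
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    tets = remap[tets]

    vols = CellMesh(nodes, tets, np.zeros(len(tets), int), np.empty((0, 3), int),
                    np.empty(0, int), np.empty(0, int)).tet_volumes()
    if np.any(vols <= 0):
        raise MeshError("inverted elements after orientation fix")

    # region labels: fraction of fixed interior sample points inside the nucleus
    bary_samples = np.array([
        [0.25, 0.25, 0.25, 0.25],
        [0.70, 0.10, 0.10, 0.10],
        [0.10, 0.70, 0.10, 0.10],
        [0.10, 0.10, 0.70, 0.10],
        [0.10, 0.10, 0.10, 0.70],
        [0.40, 0.40, 0.10, 0.10],
        [0.10, 0.40, 0.40, 0.10],
        [0.10, 0.10, 0.40, 0.40],
        [0.40, 0.10, 0.10, 0.40],
        [0.40, 0.10, 0.40, 0.10],
    ])
    pn = nodes[tets]  # (m,4,3)
    samp = np.einsum("sk,mkd->msd", bary_samples, pn)
    inside = (
        ((samp[..., 0] - ncx) / an) ** 2
        + ((samp[..., 1] - ncy) / bn) ** 2
        + ((samp[..., 2] - ncz) / cn) ** 2
    ) <= 1.0
    frac = inside.mean(axis=1)
    region = (frac >= 0.5).astype(int)  # 1 = nucleus

    faces, owners = _boundary_faces(tets)
    ztol = 1e-6 * c
    zface = nodes[faces][:, :, 2]
    apical = ~np.all(zface < ztol, axis=1)
    membrane_faces = faces[apical]
    membrane_owner = owners[apical]
    base_nodes = np.where(nodes[:, 2] < ztol)[0]
    if len(base_nodes) < 3:
        raise MeshError("base node set is degenerate")

    return CellMesh(
        nodes=nodes, tets=tets, region=region,
        membrane_faces=membrane_faces, membrane_owner=membrane_owner,
        base_nodes=base_nodes, cell_semi_axes=(a, b, c),
    )


def build_box_mesh(
    lx: float = 1.0, ly: float = 1.0, lz: float = 1.0,
    nx: int = 2, ny: int = 2, nz: int = 2,
    region: str = "cytoplasm",
) -> CellMesh:
    """Structured box mesh (each cube split into 6 conforming tets).

    Used for verification (patch tests, relaxation tests): the 'membrane'
    face set is the top surface z = lz, and ``base_nodes`` is the bottom.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    kuhn = [
        (0, 1, 3, 7), (0, 1, 5, 7), (0, 4, 5, 7),
        (0, 2, 3, 7), (0, 2, 6, 7), (0, 4, 6, 7),
    ]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = [
                    nid(i, j, k), nid(i, j, k + 1),
                    nid(i, j + 1, k), nid(i, j + 1, k + 1),
                    nid(i + 1, j, k), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k), nid(i + 1, j + 1, k + 1),
                ]
                for t in kuhn:
                    tets.append([corner[v] for v in t])
    tets = _fix_orientation(nodes, np.asarray(tets, dtype=int))

    faces, owners = _boundary_faces(tets)
    zface = nodes[faces][:, :, 2]
    top = np.all(np.abs(zface - lz) < 1e-9 * max(lz, 1.0), axis=1)
    base_nodes = np.where(nodes[:, 2] < 1e-9 * max(lz, 1.0))[0]
    reg = np.full(len(tets), REGIONS.index(region), dtype=int)
    return CellMesh(
        nodes=nodes, tets=tets, region=reg,
        membrane_faces=faces[top], membrane_owner=owners[top],
        base_nodes=base_nodes, cell_semi_axes=None,
    )


def _point_bary(mesh: CellMesh, pts: np.ndarray, Tinv: np.ndarray | None = None):
    """Host tet and barycentric coordinates for each query point.

    Brute-force vectorised search; returns (tet_index, bary(4)) with
    tet_index -1 when a point lies outside the mesh.
    """
    p0 = mesh.nodes[mesh.tets[:, 0]]
    if Tinv is None:
        edges = np.stack(
            [mesh.nodes[mesh.tets[:, i]] - p0 for i in (1, 2, 3)], axis=-1
        )  # (m,3,3)
        Tinv = np.linalg.inv(edges)
    out_tet = np.full(len(pts), -1, dtype=int)
    out_bary = np.zeros((len(pts), 4))
    tol = 1e-9
    for i, p in enumerate(np.asarray(pts, dtype=float)):
        lam = np.einsum("mij,mj->mi", Tinv, p - p0)  # (m,3)
        lam0 = 1.0 - lam.sum(axis=1)
        ok = (lam.min(axis=1) >= -tol) & (lam0 >= -tol)
        idx = np.flatnonzero(ok)
        if idx.size:
            j = idx[0]
            out_tet[i] = j
            out_bary[i] = np.array([lam0[j], lam[j, 0], lam[j, 1], lam[j, 2]])
    return out_tet, out_bary


def add_filaments(
    mesh: CellMesh,
    alpha: float,
    n_filaments: int = 8,
    axial_modulus: float = 2.0e9,  # Pa
    filament_radius: float = 3.5e-3,  # um (single actin filament)
    bundle_factor: float = 50.0,
    layer_height: float = 0.6,  # um above the adhesion plane
    segment_length: float | None = None,
    margin: float = 0.97,
) -> CellMesh:
    """Embed parallel basal stress-fiber truss chains at angle alpha.

    ``n_filaments`` parallel straight chains run across the basal footprint
    at height ``layer_height``, each making angle ``alpha`` (degrees, in
    [0, 90]) with the cell long (+x) axis.  Axial rigidity is
    ``axial_modulus * bundle_factor * pi * filament_radius**2`` — a bundle of
    ``bundle_factor`` actin filaments.  Chains that find no room inside the
    footprint are clipped with a warning.  Returns the same mesh object with
    ``filaments`` populated; ``n_filaments=0`` leaves it unchanged.
    """
    if not (0.0 <= alpha <= 90.0):
        raise ValueError("alpha must lie in [0, 90] degrees")
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    if n_filaments == 0:
        return mesh
    if mesh.cell_semi_axes is None:
        raise MeshError("filaments require a cell mesh with known semi-axes")
    a, b, c = mesh.cell_semi_axes
    zf = layer_height
    if not (0 < zf < c):
        raise ValueError("layer_height must lie inside the cell height")
    shrink = math.sqrt(max(1.0 - (zf / c) ** 2, 0.0))
    af, bf = margin * a * shrink, margin * b * shrink

    th = math.radians(alpha)
    d = np.array([math.cos(th), math.sin(th), 0.0])
    e = np.array([-math.sin(th), math.cos(th), 0.0])
    # support half-width of the footprint ellipse perpendicular to d
    R = math.sqrt((af * e[0]) ** 2 + (bf * e[1]) ** 2)
    offsets = np.linspace(-0.8 * R, 0.8 * R, n_filaments)
    if segment_length is None:
        segment_length = 0.075 * max(a, b)
    EA = axial_modulus * bundle_factor * math.pi * filament_radius**2

    p0 = mesh.nodes[mesh.tets[:, 0]]
    edges = np.stack(
        [mesh.nodes[mesh.tets[:, i]] - p0 for i in (1, 2, 3)], axis=-1
    )
    Tinv = np.linalg.inv(edges)

    trusses: list[EmbeddedTruss] = []
    clipped = 0
    for off in offsets:
        o = off * e
        # line o + t d intersected with (x/af)^2 + (y/bf)^2 = 1
        A = (d[0] / af) ** 2 + (d[1] / bf) ** 2
        B2 = 2.0 * (o[0] * d[0] / af**2 + o[1] * d[1] / bf**2)
        C = (o[0] / af) ** 2 + (o[1] / bf) ** 2 - 1.0
        disc = B2 * B2 - 4 * A * C
        if disc <= 0:
            clipped += 1
            continue
        t1 = (-B2 - math.sqrt(disc)) / (2 * A)
        t2 = (-B2 + math.sqrt(disc)) / (2 * A)
        L = t2 - t1
        nseg = max(1, int(round(L / segment_length)))
        ts = np.linspace(t1, t2, nseg + 1)
        pts = o[None, :] + ts[:, None] * d[None, :]
        pts[:, 2] = zf
        host, bary = _point_bary(mesh, pts, Tinv)
        for i in range(nseg):
            if host[i] < 0 or host[i + 1] < 0:
                clipped += 1
                continue
            seg = pts[i + 1] - pts[i]
            ln = float(np.linalg.norm(seg))
            if ln <= 0:
                continue
            trusses.append(EmbeddedTruss(
                tet_a=int(host[i]), bary_a=bary[i].copy(),
                tet_b=int(host[i + 1]), bary_b=bary[i + 1].copy(),
                direction=seg / ln, length=ln, EA=EA,
            ))
    if clipped:
        warnings.warn(f"{clipped} filament segment(s) clipped at the basal "
                      "footprint boundary")
    mesh.filaments = mesh.filaments + trusses
    return mesh


def write_vtk(mesh: CellMesh, path) -> None:
    """Write the tet mesh with region labels as legacy ASCII VTK."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncytomech cell mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        f.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for t in mesh.tets:
            f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        f.write("\n".join(["10"] * mesh.n_elements) + "\n")
        f.write(f"CELL_DATA {mesh.n_elements}\nSCALARS region int 1\n")
        f.write("LOOKUP_TABLE default\n")
        f.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
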