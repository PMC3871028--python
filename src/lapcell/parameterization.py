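"""Spherical parameterization of genus-zero voxel surfaces.

The boundary of a topology-fixed binary volume is extracted as a closed,
2-manifold triangle mesh (voxel boundary quads split into triangles).  An
initial bijection onto the unit sphere is computed from two Laplace solves
on the surface graph — the heat-diffusion picture: latitude θ is the
stationary temperature with the north pole held at 0 and the south pole at
π; longitude φ solves the same equation around the sphere with a 2π jump
across a pole-to-pole cut path (the date line).  The initial map is then
relaxed to reduce area distortion: vertices move on the sphere so that the
spherical area fraction of each face approaches its surface area fraction,
accepting only moves that decrease the distortion cost and never flipping
the orientation of a spherical triangle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse import linalg as sla

from .io import BinaryVolume, SurfaceMesh, log
from .topology import is_spherical


class NonSphericalVolumeError(ValueError):
    """Input volume is not genus zero; run topology fixing first."""


class ParameterizationError(RuntimeError):
    pass


@dataclasses.dataclass
class SphericalMap:
    """Per-vertex unit-sphere coordinates: polar angle θ ∈ [0, π] and
    azimuth φ ∈ [0, 2π)."""

    theta: np.ndarray
    phi: np.ndarray
    pole_north: int
    pole_south: int

    def unit_points(self) -> np.ndarray:
        st = np.sin(self.theta)
        return np.column_stack([st * np.cos(self.phi), st * np.sin(self.phi),
                                np.cos(self.theta)])


# ---------------------------------------------------------------------------
# voxel surface extraction

# quad corner offsets (lattice units) for a boundary face in direction ±axis,
# wound counter-clockwise seen from outside (normal pointing away from the voxel)
_FACE_CORNERS = {
    (0, +1): [(1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)],
    (0, -1): [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)],
    (1, +1): [(0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)],
    (1, -1): [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)],
    (2, +1): [(0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
    (2, -1): [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)],
}


def _boundary_quads(mask: np.ndarray):
    """Yield (voxel index array, axis, sign) for every exposed face."""
    out = []
    for axis in range(3):
        for sign in (+1, -1):
            shifted = np.roll(np.pad(mask, 1), -sign, axis=axis)[1:-1, 1:-1, 1:-1]
            exposed = mask & ~shifted
            out.append((np.argwhere(exposed), axis, sign))
    return out


def _build_voxel_surface(mask: np.ndarray, spacing) -> SurfaceMesh:
    vindex: dict[tuple, int] = {}
    verts: list[tuple] = []
    faces = []

    def vid(p):
        i = vindex.get(p)
        if i is None:
            i = len(verts)
            vindex[p] = i
            verts.append(p)
        return i

    for voxels, axis, sign in _boundary_quads(mask):
        corners = _FACE_CORNERS[(axis, sign)]
        for v in voxels:
            c = [vid((v[0] + o[0], v[1] + o[1], v[2] + o[2])) for o in corners]
            # fixed-diagonal split of the quad, consistent winding
            faces.append((c[0], c[1], c[2]))
            faces.append((c[0], c[2], c[3]))
    vertices = np.asarray(verts, dtype=np.float64) * np.asarray(spacing)
    return SurfaceMesh(vertices, np.asarray(faces))


def _nonmanifold_repairs(mask: np.ndarray) -> int:
    """Thicken diagonal edge- and vertex-contacts.

    Two foreground voxels sharing only a lattice edge (diagonal pair in a
    2×2 plaquette) produce a 4-face mesh edge; two sharing only a lattice
    point (antipodal pair in a 2×2×2 block) produce a pinch vertex.  Both
    are resolved by adding one deterministic empty voxel of the
    configuration.  Returns the number of voxels added.
    """
    added = 0

    def _corner(offs):
        """View of all 2×2(×2) block corners at the given 0/1 offsets."""
        return mask[tuple(slice(o, mask.shape[ax] - 1 + o) if o is not None
                          else slice(None) for ax, o in enumerate(offs))]

    # edge contacts: plaquette perpendicular to each pair of axes
    for a1, a2 in ((0, 1), (0, 2), (1, 2)):
        offs = [None, None, None]

        def plaq(o1, o2):
            offs_ = list(offs)
            offs_[a1], offs_[a2] = o1, o2
            return _corner(offs_)

        p00, p01 = plaq(0, 0), plaq(0, 1)
        p10, p11 = plaq(1, 0), plaq(1, 1)
        for bad, da1, da2 in ((p00 & p11 & ~p01 & ~p10, 0, 1),
                              (p01 & p10 & ~p00 & ~p11, 0, 0)):
            for idx in np.argwhere(bad):
                coord = idx.copy()
                coord[a1] += da1
                coord[a2] += da2
                if not mask[tuple(coord)]:
                    mask[tuple(coord)] = True
                    added += 1

    # vertex contacts: antipodal foreground pair alone in its 2×2×2 block,
    # or antipodal background pair in an otherwise-full block (a background
    # pinch, equally non-manifold); both are fixed by filling one voxel
    blocks = {offs: _corner(offs) for offs in
              [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]}
    occupancy = sum(b.astype(np.int8) for b in blocks.values())
    for o in ((0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)):
        anti = tuple(1 - x for x in o)
        bad_fg = blocks[o] & blocks[anti] & (occupancy == 2)
        bad_bg = ~blocks[o] & ~blocks[anti] & (occupancy == 6)
        for bad, fill in ((bad_fg, (o[0], o[1], 1 - o[2])), (bad_bg, o)):
            for idx in np.argwhere(bad):
                coord = idx + np.asarray(fill)
                if not mask[tuple(coord)]:
                    mask[tuple(coord)] = True
                    added += 1
    return added


def _vertex_fans_ok(mesh: SurfaceMesh) -> np.ndarray:
    """Boolean per vertex: incident faces form a single edge-connected fan."""
    v2f: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for fi, f in enumerate(mesh.faces):
        for v in f:
            v2f[v].append(fi)
    ok = np.ones(mesh.n_vertices, dtype=bool)
    faces = mesh.faces
    for v, flist in enumerate(v2f):
        if len(flist) <= 1:
            ok[v] = len(flist) == 1
            continue
        # connect faces sharing an edge through v
        succ = {}
        for fi in flist:
            a, b, c = faces[fi]
            tri = [a, b, c]
            j = tri.index(v)
            succ[tri[(j + 1) % 3]] = tri[(j + 2) % 3]
        start = next(iter(succ))
        cnt, cur = 0, start
        while True:
            cur = succ.get(cur)
            cnt += 1
            if cur is None or cnt > len(flist):
                ok[v] = False
                break
            if cur == start:
                ok[v] = cnt == len(flist)
                break
    return ok


def extract_surface(vol: BinaryVolume) -> SurfaceMesh:
    """Closed 2-manifold triangle mesh of the voxel boundary (χ = 2).

    Non-manifold edge/vertex contacts between diagonal voxels are resolved
    by a thickening pre-pass that adds the minimal voxel set (logged).
    """
    if not is_spherical(vol):
        raise NonSphericalVolumeError(
            "volume is not genus zero; run topology fixing first")
    mask = vol.mask.copy()
    total_added = 0
    mesh = None
    for _ in range(10):
        for _ in range(20):
            added = _nonmanifold_repairs(mask)
            total_added += added
            if added == 0:
                break
        mesh = _build_voxel_surface(mask, vol.spacing)
        fans = _vertex_fans_ok(mesh)
        if mesh.is_closed_manifold() and bool(fans.all()):
            break
        # remaining pinch vertices: fill the first empty voxel incident to each
        fixed_any = False
        spacing = np.asarray(vol.spacing)
        for v in np.nonzero(~fans)[0]:
            p = np.rint(mesh.vertices[v] / spacing).astype(int)
            for d in np.ndindex(2, 2, 2):
                c = p - np.asarray(d)
                if np.all(c >= 0) and np.all(c < mask.shape) and not mask[tuple(c)]:
                    mask[tuple(c)] = True
                    total_added += 1
                    fixed_any = True
                    break
        if not fixed_any:
            break
    if total_added:
        log.info("surface extraction thickened %d voxels to restore manifoldness",
                 total_added)
    if mesh is None or not mesh.is_closed_manifold() or not bool(_vertex_fans_ok(mesh).all()):
        raise ParameterizationError("voxel surface is not a closed 2-manifold")
    chi = mesh.euler_characteristic()
    if chi != 2:
        raise ParameterizationError(f"surface has Euler characteristic {chi} != 2")
    return mesh


# ---------------------------------------------------------------------------
# surface graph utilities


def _surface_laplacian(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Combinatorial (unit-weight) graph Laplacian of the mesh edges."""
    e = mesh.edges()
    n = mesh.n_vertices
    ones = np.ones(len(e))
    A = sparse.coo_matrix((np.concatenate([ones, ones]),
                           (np.concatenate([e[:, 0], e[:, 1]]),
                            np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n)).tocsr()
    return (sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A).tocsr()


def select_poles(mesh: SurfaceMesh) -> tuple[int, int]:
    """Two vertices of maximal extent along the principal axis of the
    vertex cloud."""
    pts = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    proj = pts @ vt[0]
    north, south = int(np.argmax(proj)), int(np.argmin(proj))
    if north == south:
        raise ParameterizationError("degenerate vertex cloud; poles coincide")
    return north, south


def initial_latitude(mesh: SurfaceMesh, poles: tuple[int, int] | None = None) -> np.ndarray:
    """Latitude as the stationary heat distribution: θ = 0 at the north
    pole, π at the south pole, harmonic elsewhere."""
    if poles is None:
        poles = select_poles(mesh)
    north, south = poles
    if north == south:
        raise ParameterizationError("poles coincide")
    L = _surface_laplacian(mesh)
    n = mesh.n_vertices
    free = np.ones(n, dtype=bool)
    free[[north, south]] = False
    theta = np.zeros(n)
    theta[south] = np.pi
    rhs = -L[free][:, [north, south]] @ theta[[north, south]]
    theta[free] = sla.spsolve(L[free][:, free].tocsc(), rhs)
    return theta


def _cut_path(mesh: SurfaceMesh, north: int, south: int) -> list[int]:
    """Shortest edge path from north to south pole (the date line)."""
    e = mesh.edges()
    n = mesh.n_vertices
    ones = np.ones(len(e))
    A = sparse.coo_matrix((np.concatenate([ones, ones]),
                           (np.concatenate([e[:, 0], e[:, 1]]),
                            np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n)).tocsr()
    _, pred = csgraph.shortest_path(A, indices=[north], return_predecessors=True,
                                    unweighted=True)
    path = [south]
    while path[-1] != north:
        p = pred[0, path[-1]]
        if p < 0:
            raise ParameterizationError("no edge path between poles")
        path.append(int(p))
    return path[::-1]  # north ... south


def _cyclic_neighbors(mesh: SurfaceMesh, v: int, v2f) -> dict[int, int]:
    """Successor map u→w meaning face (v, u, w) exists: walking succ follows
    the oriented one-ring of v."""
    succ = {}
    for fi in v2f[v]:
        a, b, c = mesh.faces[fi]
        tri = [int(a), int(b), int(c)]
        j = tri.index(v)
        succ[tri[(j + 1) % 3]] = tri[(j + 2) % 3]
    return succ


def initial_longitude(mesh: SurfaceMesh, theta: np.ndarray,
                      poles: tuple[int, int] | None = None) -> np.ndarray:
    """Longitude by a Laplace solve with a 2π jump across the date line.

    The cut path (shortest pole-to-pole edge path) is pinned at φ = 0;
    neighbours on the west side of the cut see the cut at 2π instead, which
    places a ±2π offset on every cut-crossing edge of the linear system.
    Poles are excluded (their φ is undefined) and the result is wrapped to
    [0, 2π).
    """
    if poles is None:
        poles = select_poles(mesh)
    north, south = poles
    path = _cut_path(mesh, north, south)
    on_path = np.zeros(mesh.n_vertices, dtype=bool)
    on_path[path] = True

    v2f: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for fi, f in enumerate(mesh.faces):
        for v in f:
            v2f[v].append(fi)

    # classify the west-side neighbours of each interior date-line vertex:
    # in the oriented one-ring, the arc from the next path vertex to the
    # previous path vertex (exclusive) is one bank of the cut
    west_pairs: set[tuple[int, int]] = set()   # (dateline vertex, west neighbour)
    for i in range(1, len(path) - 1):
        d = path[i]
        prv, nxt = path[i - 1], path[i + 1]
        succ = _cyclic_neighbors(mesh, d, v2f)
        # oriented one-ring: the arc from the previous to the next path
        # vertex is the bank on which φ approaches 2π (keeps the final map
        # orientation-preserving with θ measured from the north pole)
        cur = prv
        guard = 0
        while True:
            cur = succ[cur]
            guard += 1
            if cur == nxt or guard > len(succ) + 1:
                break
            west_pairs.add((d, cur))

    L = _surface_laplacian(mesh).tolil()
    n = mesh.n_vertices
    is_pole = np.zeros(n, dtype=bool)
    is_pole[[north, south]] = True
    # poles carry no longitude: remove them from the graph entirely
    free = ~(on_path | is_pole)
    rhs = np.zeros(n)
    for d, w in west_pairs:
        if not is_pole[w] and not on_path[w]:
            rhs[w] += 2.0 * np.pi  # w sees the date line at 2π, not 0
    L = L.tocsr()
    # drop pole columns/rows: subtract pole adjacency from degrees
    A = sparse.diags(L.diagonal()) - L  # adjacency
    A = A.tolil()
    A[:, [north, south]] = 0
    A[[north, south], :] = 0
    A = A.tocsr()
    Lred = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    phi = np.zeros(n)
    sys = Lred[free][:, free].tocsc()
    b = rhs[free] - Lred[free][:, ~free] @ phi[~free]
    phi[free] = sla.spsolve(sys, b)
    phi = np.mod(phi, 2.0 * np.pi)
    return phi


# ---------------------------------------------------------------------------
# area-distortion optimization


def spherical_triangle_areas(u: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed spherical areas (spherical excess with the sign of the
    orientation) of unit-vector triangles."""
    a, b, c = u[faces[:, 0]], u[faces[:, 1]], u[faces[:, 2]]
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    denom = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) \
        + np.einsum("ij,ij->i", c, a)
    e = 2.0 * np.arctan2(np.abs(det), denom)
    return np.where(det >= 0, e, -e)


def triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def area_distortion_cost(u: np.ndarray, faces: np.ndarray,
                         surf_frac: np.ndarray) -> float:
    sph = spherical_triangle_areas(u, faces)
    d = sph / (4.0 * np.pi) - surf_frac
    return float(np.sum(d * d))


def count_flipped(u: np.ndarray, faces: np.ndarray) -> int:
    return int(np.sum(spherical_triangle_areas(u, faces) <= 0.0))


def optimize_area(mesh: SurfaceMesh, init: SphericalMap,
                  max_iter: int = 200, tol: float = 1e-10,
                  step0: float = 0.5) -> SphericalMap:
    """Accept-only-improving relaxation of the area-distortion cost
    Σ_f (spherical_frac_f − surface_frac_f)².

    Each sweep moves every non-pole vertex along a pulled direction — toward
    the spherical centroids of incident faces that are too large on the
    sphere and away from those too small — projected back to the sphere.
    A sweep is accepted only if the global cost decreases and no spherical
    triangle flips orientation; otherwise the step is halved.
    """
    faces = mesh.faces
    surf = triangle_areas(mesh.vertices, faces)
    surf_frac = surf / surf.sum()
    u = init.unit_points()

    # untangling pre-passes: local damped smoothing of only the vertices of
    # flipped triangles (global smoothing would distort the valid majority)
    nflip = count_flipped(u, faces)
    if nflip:
        e = mesh.edges()
        n = mesh.n_vertices
        ones = np.ones(len(e))
        A = sparse.coo_matrix((np.concatenate([ones, ones]),
                               (np.concatenate([e[:, 0], e[:, 1]]),
                                np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n)).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        fixed = np.zeros(n, dtype=bool)
        fixed[[init.pole_north, init.pole_south]] = True
        for _ in range(500):
            flipped = spherical_triangle_areas(u, faces) <= 0.0
            if not flipped.any():
                break
            moving = np.zeros(n, dtype=bool)
            moving[faces[flipped].ravel()] = True
            moving &= ~fixed
            avg = A[moving] @ u / deg[moving, None]
            u_new = u.copy()
            u_new[moving] = 0.5 * u[moving] + 0.5 * avg
            norms = np.linalg.norm(u_new, axis=1, keepdims=True)
            u = np.where(norms > 1e-12, u_new / norms, u)
        nflip = count_flipped(u, faces)
        if nflip:
            log.warning("area optimization starts with %d flipped triangles", nflip)

    cost = area_distortion_cost(u, faces, surf_frac)
    fixed = np.zeros(len(u), dtype=bool)
    fixed[[init.pole_north, init.pole_south]] = True
    step = step0
    n_verts = len(u)
    for _ in range(max_iter):
        sph = spherical_triangle_areas(u, faces)
        excess = sph / (4.0 * np.pi) - surf_frac  # >0: face too large on sphere
        cent = (u[faces[:, 0]] + u[faces[:, 1]] + u[faces[:, 2]]) / 3.0
        cn = np.linalg.norm(cent, axis=1, keepdims=True)
        cent = cent / np.maximum(cn, 1e-12)
        move = np.zeros_like(u)
        wsum = np.zeros(n_verts)
        for k in range(3):
            idx = faces[:, k]
            np.add.at(move, idx, excess[:, None] * (cent - u[idx]))
            np.add.at(wsum, idx, np.abs(excess))
        scale = np.where(wsum > 1e-15, 1.0 / (wsum + 1e-15), 0.0)
        move *= scale[:, None]
        accepted = False
        s = step
        for _ in range(12):
            u_try = u + s * move
            u_try[fixed] = u[fixed]
            norms = np.linalg.norm(u_try, axis=1, keepdims=True)
            u_try = u_try / np.maximum(norms, 1e-12)
            if count_flipped(u_try, faces) <= nflip:
                c_try = area_distortion_cost(u_try, faces, surf_frac)
                if c_try < cost:
                    improvement = cost - c_try
                    u, cost = u_try, c_try
                    nflip = count_flipped(u, faces)
                    accepted = True
                    step = min(s * 1.3, 1.0)
                    break
            s *= 0.5
        if not accepted:
            break
        if improvement < tol:
            break

    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * np.pi)
    theta[init.pole_north] = init.theta[init.pole_north]
    theta[init.pole_south] = init.theta[init.pole_south]
    phi[init.pole_north] = init.phi[init.pole_north]
    phi[init.pole_south] = init.phi[init.pole_south]
    return SphericalMap(theta=theta, phi=phi, pole_north=init.pole_north,
                        pole_south=init.pole_south)


def parameterize(vol_or_mesh, max_iter: int = 200) -> tuple[SurfaceMesh, SphericalMap]:
    """Full chain: surface extraction (for volumes) + initialization +
    area-distortion optimization.

    The initial map orients the sphere so that θ comes from the latitude
    solve and φ from the longitude solve directly.
    """
    if isinstance(vol_or_mesh, BinaryVolume):
        mesh = extract_surface(vol_or_mesh)
    else:
        mesh = vol_or_mesh
    poles = select_poles(mesh)
    theta = initial_latitude(mesh, poles)
    phi = initial_longitude(mesh, theta, poles)
    init = SphericalMap(theta=theta, phi=phi, pole_north=poles[0], pole_south=poles[1])
    final = optimize_area(mesh, init, max_iter=max_iter)
    return mesh, final
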