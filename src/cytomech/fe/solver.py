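"""Quasi-static viscoelastic finite-element solver.

Linear 4-node tetrahedra with a one-term Prony (standard linear solid)
shear relaxation and elastic bulk response; embedded truss filaments add
elastic axial stiffness.  Two loading modes are supported:

``pressure``
    A dead pressure applied normal to the apical membrane faces with
    magnitude  mean + amplitude * sin(2 pi f t).  Used for verification
    (patch tests) and free-surface studies.

``platen``
    Rigid no-slip platen contact on the apex: the stiff agarose overlay is
    ~25x stiffer than the cell, so the contact acts as a prescribed
    vertical displacement on the apical cap (nodes above a height
    fraction), with in-plane motion suppressed by adhesion/friction.  The
    platen displacement is calibrated by force balance: the displacement
    delta(sigma) at which the total vertical reaction equals the applied
    stress times the cell footprint area (long-term stiffness).

The base nodes are fixed.  Time integration uses the exact exponential
recurrence for the internal deviatoric variables (strain assumed linear
within a step), so each step costs one sparse back-substitution with a
constant factorised effective stiffness.

Membrane summary metrics (average / peak maximum principal strain) are
evaluated at the cycle-maximum load of the final cycle, area-weighted over
the apical element layer, excluding elements that touch a constrained node
(their strain is dominated by the boundary-condition singularity, not by
the solution field).

Units: length um, stress Pa, time s; forces are Pa*um^2.
Voigt order: [xx, yy, zz, xy, yz, zx] with engineering shear strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .materials import DEFAULT_MATERIALS, PronyMaterial
from .mesh import REGIONS, CellMesh

_VOIGT_W = np.array([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])  # dev stress weights
_M = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])

# unit-shear deviatoric stiffness: s = G * D_DEV @ eps (engineering shear)
_D_DEV = np.array([
    [4 / 3, -2 / 3, -2 / 3, 0, 0, 0],
    [-2 / 3, 4 / 3, -2 / 3, 0, 0, 0],
    [-2 / 3, -2 / 3, 4 / 3, 0, 0, 0],
    [0, 0, 0, 1.0, 0, 0],
    [0, 0, 0, 0, 1.0, 0],
    [0, 0, 0, 0, 0, 1.0],
])


class SingularSystemError(RuntimeError):
    """Stiffness is singular (insufficient constraints)."""


@dataclass
class LoadSpec:
    """Sinusoidal (or static, frequency 0) compressive load in Pa."""

    mean_stress: float
    amplitude: float = 0.0
    frequency: float = 0.0  # Hz; 0 = static
    duration: float | None = None  # s; default chosen by the solver

    def __post_init__(self) -> None:
        if not (self.mean_stress >= self.amplitude >= 0.0):
            raise ValueError("require mean_stress >= amplitude >= 0")
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")

    def pressure(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.mean_stress + self.amplitude * np.sin(
            2.0 * math.pi * self.frequency * t
        )


@dataclass
class StrainReport:
    """Strain history on a recorded element set plus membrane summaries.

    ``interior_mask`` flags recorded elements that touch no constrained
    node; summary metrics are computed over this subset.
    """

    times: np.ndarray  # (nt,)
    load_values: np.ndarray  # (nt,) applied stress in Pa
    element_ids: np.ndarray  # (k,) recorded tets (membrane layer by default)
    strain_history: np.ndarray  # (nt, k, 6) Voigt
    areas: np.ndarray  # (k,) apical face area per recorded element (0 if none)
    interior_mask: np.ndarray  # (k,) bool
    frequency: float = 0.0
    avg_max_principal: float = math.nan
    peak_max_principal: float = math.nan
    evaluation_time: float = math.nan

    def max_principal_history(self) -> np.ndarray:
        """(nt, k) largest principal strain per recorded element and time."""
        return max_principal_strain(self.strain_history)

    def membrane_strains_at_eval(self) -> np.ndarray:
        """Max principal strain of the evaluated (interior) membrane
        elements at the evaluation instant — the damage-statistic input."""
        n_eval = int(np.argmin(np.abs(self.times - self.evaluation_time)))
        mp = max_principal_strain(self.strain_history[n_eval])
        return mp[self.interior_mask]


def max_principal_strain(voigt: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of the small-strain tensor(s) given in Voigt form."""
    v = np.asarray(voigt, dtype=float)
    shp = v.shape[:-1]
    v = v.reshape(-1, 6)
    T = np.empty((len(v), 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = v[:, 0], v[:, 1], v[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = v[:, 3] / 2.0
    T[:, 1, 2] = T[:, 2, 1] = v[:, 4] / 2.0
    T[:, 0, 2] = T[:, 2, 0] = v[:, 5] / 2.0
    ev = np.linalg.eigvalsh(T)
    return ev[:, -1].reshape(shp)


@dataclass
class FESystem:
    """Assembled system: element operators, loads, constraints, materials."""

    mesh: CellMesh
    B: np.ndarray  # (m, 6, 12)
    vol: np.ndarray  # (m,)
    dofmap: np.ndarray  # (m, 12)
    G0: np.ndarray  # (m,) Pa
    G_inf: np.ndarray  # (m,) Pa
    K_bulk: np.ndarray  # (m,) Pa
    tau: np.ndarray  # (m,) s
    f_unit: np.ndarray  # (ndof,) load for unit apical pressure (pressure mode)
    free: np.ndarray  # free dof indices
    constrained_nodes: np.ndarray  # nodes with any fixed/prescribed dof
    prescribed_dofs: np.ndarray  # platen dofs (empty in pressure mode)
    prescribed_unit: np.ndarray  # their values for unit platen displacement
    delta_per_pa: float = 0.0  # platen displacement per Pa of applied stress
    K_vol_rows: np.ndarray = field(repr=False, default=None)
    K_vol_cols: np.ndarray = field(repr=False, default=None)
    K_vol_vals: np.ndarray = field(repr=False, default=None)  # bulk part
    K_dev_vals: np.ndarray = field(repr=False, default=None)  # per unit G
    truss_rows: np.ndarray = field(repr=False, default=None)
    truss_cols: np.ndarray = field(repr=False, default=None)
    truss_vals: np.ndarray = field(repr=False, default=None)

    @property
    def ndof(self) -> int:
        return 3 * self.mesh.n_nodes

    def _combine(self, G: np.ndarray,
                 include_truss: bool = True) -> sparse.csc_matrix:
        vals = self.K_vol_vals + G.repeat(144) * self.K_dev_vals
        if include_truss:
            rows = np.concatenate([self.K_vol_rows, self.truss_rows])
            cols = np.concatenate([self.K_vol_cols, self.truss_cols])
            data = np.concatenate([vals, self.truss_vals])
        else:
            rows, cols, data = self.K_vol_rows, self.K_vol_cols, vals
        return sparse.coo_matrix((data, (rows, cols)),
                                 shape=(self.ndof, self.ndof)).tocsc()

    def effective_stiffness(self, dt: float) -> sparse.csc_matrix:
        """K(dt) = K_bulk + G_eff(dt) K_dev + K_truss on all dofs."""
        beta = np.exp(-dt / self.tau)
        gamma = (self.tau / dt) * (1.0 - beta)
        G_eff = self.G_inf + (self.G0 - self.G_inf) * gamma
        return self._combine(G_eff)

    def elastic_stiffness(self, which: str = "instantaneous") -> sparse.csc_matrix:
        """Purely elastic limit stiffness (G0 or G_inf) plus trusses."""
        return self._combine(self.G0 if which == "instantaneous" else self.G_inf)


def _element_operators(mesh: CellMesh):
    p = mesh.nodes[mesh.tets]  # (m,4,3)
    e = np.stack([p[:, i] - p[:, 0] for i in (1, 2, 3)], axis=2)  # cols = edges
    det = np.linalg.det(e)
    vol = det / 6.0
    if np.any(vol <= 0):
        raise ValueError("non-positive tet volume")
    einv = np.linalg.inv(e)  # rows are grad(lambda_1..3)
    g = np.empty((len(p), 4, 3))
    g[:, 1:, :] = einv
    g[:, 0, :] = -einv.sum(axis=1)
    B = np.zeros((len(p), 6, 12))
    for i in range(4):
        gx, gy, gz = g[:, i, 0], g[:, i, 1], g[:, i, 2]
        B[:, 0, 3 * i + 0] = gx
        B[:, 1, 3 * i + 1] = gy
        B[:, 2, 3 * i + 2] = gz
        B[:, 3, 3 * i + 0] = gy
        B[:, 3, 3 * i + 1] = gx
        B[:, 4, 3 * i + 1] = gz
        B[:, 4, 3 * i + 2] = gy
        B[:, 5, 3 * i + 0] = gz
        B[:, 5, 3 * i + 2] = gx
    dofmap = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    return B, vol, dofmap


def _pressure_load(mesh: CellMesh) -> np.ndarray:
    """Consistent nodal load for unit pressure pushing on the apical faces."""
    f = np.zeros(3 * mesh.n_nodes)
    if len(mesh.membrane_faces) == 0:
        return f
    tri = mesh.nodes[mesh.membrane_faces]  # (k,3,3)
    n = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    cent = tri.mean(axis=1)
    own = mesh.tets[mesh.membrane_owner]
    opp = np.empty((len(own), 3))
    for i, (t, face) in enumerate(zip(own, mesh.membrane_faces)):
        rest = [v for v in t if v not in set(face)]
        opp[i] = mesh.nodes[rest[0]] if rest else cent[i]
    flip = np.einsum("ij,ij->i", n, cent - opp) < 0
    n[flip] *= -1.0
    nodal = -n / 3.0  # pressure acts opposite the outward normal
    for j in range(3):
        for cmp in range(3):
            np.add.at(f, 3 * mesh.membrane_faces[:, j] + cmp, nodal[:, cmp])
    return f


def assemble_viscoelastic(
    mesh: CellMesh,
    materials: dict[str, PronyMaterial] | None = None,
    fixed_dofs: np.ndarray | None = None,
    contact: str | None = None,
    contact_frac: float = 0.8,
    friction: bool = True,
    prescribed_dofs: np.ndarray | None = None,
    prescribed_unit: np.ndarray | None = None,
) -> FESystem:
    """Build element operators, load vector and stiffness ingredients.

    ``materials`` maps region names ('cytoplasm', 'nucleus') to
    :class:`PronyMaterial`; every region present in the mesh must have one.
    ``fixed_dofs`` defaults to all three components of the base nodes.
    ``contact='platen'`` switches from dead apical pressure to prescribed
    vertical displacement on nodes above ``contact_frac`` of the cell
    height (with in-plane motion suppressed when ``friction`` is True) and
    calibrates the displacement-per-stress factor by force balance over the
    cell footprint.  Explicit ``prescribed_dofs``/``prescribed_unit``
    (displacement-controlled tests) scale the unit pattern directly by the
    load magnitude.  Raises :class:`SingularSystemError` if unconstrained.
    """
    if materials is None:
        materials = DEFAULT_MATERIALS
    present = np.unique(mesh.region)
    for r in present:
        if REGIONS[r] not in materials:
            raise ValueError(f"no material for region '{REGIONS[r]}'")
    B, vol, dofmap = _element_operators(mesh)
    m = len(vol)
    G0 = np.empty(m)
    G_inf = np.empty(m)
    K_bulk = np.empty(m)
    tau = np.empty(m)
    for r in present:
        mat = materials[REGIONS[r]]
        sel = mesh.region == r
        G0[sel] = mat.G0_pa
        G_inf[sel] = mat.G_inf_pa
        K_bulk[sel] = mat.bulk_modulus_pa
        tau[sel] = mat.tau

    Bm = np.einsum("eij,i->ej", B, _M)  # (m,12): m' B
    Kv = vol[:, None, None] * K_bulk[:, None, None] * np.einsum(
        "ei,ej->eij", Bm, Bm
    )
    DB = np.einsum("ij,ejk->eik", _D_DEV, B)
    Kd = vol[:, None, None] * np.einsum("eji,ejk->eik", B, DB)
    rows = np.repeat(dofmap, 12, axis=1).ravel()
    cols = np.tile(dofmap, (1, 12)).ravel()

    trows, tcols, tvals = [], [], []
    for tr in mesh.filaments:
        D3 = np.outer(tr.direction, tr.direction) * (tr.EA / tr.length)
        k6 = np.block([[D3, -D3], [-D3, D3]])
        T = np.zeros((6, 24))
        dofs = np.empty(24, dtype=int)
        for s, (tet, bary) in enumerate([(tr.tet_a, tr.bary_a),
                                         (tr.tet_b, tr.bary_b)]):
            nd = mesh.tets[tet]
            for j in range(4):
                for cmp in range(3):
                    T[3 * s + cmp, 12 * s + 3 * j + cmp] = bary[j]
                    dofs[12 * s + 3 * j + cmp] = 3 * nd[j] + cmp
        Kt = T.T @ k6 @ T
        trows.append(np.repeat(dofs, 24))
        tcols.append(np.tile(dofs, 24))
        tvals.append(Kt.ravel())
    if trows:
        trows = np.concatenate(trows)
        tcols = np.concatenate(tcols)
        tvals = np.concatenate(tvals)
    else:
        trows = np.empty(0, dtype=int)
        tcols = np.empty(0, dtype=int)
        tvals = np.empty(0)

    ndof = 3 * mesh.n_nodes
    if fixed_dofs is None:
        if len(mesh.base_nodes) == 0:
            raise SingularSystemError("no base nodes and no fixed_dofs given")
        fixed_dofs = (3 * mesh.base_nodes[:, None]
                      + np.arange(3)[None, :]).ravel()
    fixed_dofs = np.unique(np.asarray(fixed_dofs, dtype=int))

    explicit_prescribed = prescribed_dofs is not None
    if not explicit_prescribed:
        prescribed_dofs = np.empty(0, dtype=int)
        prescribed_unit = np.empty(0)
    else:
        prescribed_dofs = np.asarray(prescribed_dofs, dtype=int)
        prescribed_unit = np.asarray(prescribed_unit, dtype=float)
    f_unit = np.zeros(ndof)
    if contact is None:
        if not explicit_prescribed:
            f_unit = _pressure_load(mesh)
    elif contact == "platen":
        if mesh.cell_semi_axes is None:
            raise ValueError("platen contact requires a cell mesh")
        c = mesh.cell_semi_axes[2]
        cap = np.where(mesh.nodes[:, 2] > contact_frac * c)[0]
        if cap.size == 0:
            raise ValueError("contact_frac leaves no contact nodes")
        pd = [3 * cap + 2]
        pu = [-np.ones(len(cap))]
        if friction:
            pd += [3 * cap, 3 * cap + 1]
            pu += [np.zeros(len(cap)), np.zeros(len(cap))]
        prescribed_dofs = np.concatenate(pd)
        prescribed_unit = np.concatenate(pu)
    else:
        raise ValueError(f"unknown contact mode '{contact}'")

    all_constrained = np.unique(np.concatenate([fixed_dofs, prescribed_dofs]))
    if all_constrained.size == 0:
        raise SingularSystemError("system has no constraints")
    free = np.setdiff1d(np.arange(ndof), all_constrained)
    constrained_nodes = np.unique(all_constrained // 3)

    system = FESystem(
        mesh=mesh, B=B, vol=vol, dofmap=dofmap,
        G0=G0, G_inf=G_inf, K_bulk=K_bulk, tau=tau,
        f_unit=f_unit, free=free,
        constrained_nodes=constrained_nodes,
        prescribed_dofs=prescribed_dofs, prescribed_unit=prescribed_unit,
        K_vol_rows=rows, K_vol_cols=cols, K_vol_vals=Kv.ravel(),
        K_dev_vals=Kd.ravel(),
        truss_rows=trows, truss_cols=tcols, truss_vals=tvals,
    )
    if explicit_prescribed:
        system.delta_per_pa = 1.0  # load magnitude read as displacement scale

    if contact == "platen":
        # Force balance in the long-term limit: delta such that the platen
        # reaction equals sigma * (footprint area pi a b).  The reference is
        # the continuum cell WITHOUT filament trusses: the platen position
        # is imposed by the far-field gel, so the same kinematics apply to
        # every filament architecture.
        a, b, _ = mesh.cell_semi_axes
        K = system._combine(system.G_inf, include_truss=False)
        u = np.zeros(ndof)
        u[prescribed_dofs] = prescribed_unit
        rhs = -(K[free][:, prescribed_dofs] @ prescribed_unit)
        lu = splu(K[free][:, free].tocsc())
        u[free] = lu.solve(rhs)
        f_int = K @ u
        zd = 3 * (prescribed_dofs[prescribed_unit < 0] // 3) + 2
        Rz = -f_int[np.unique(zd)].sum()
        if Rz <= 0:
            raise SingularSystemError("non-positive platen reaction")
        system.delta_per_pa = math.pi * a * b / Rz
    return system


def _deviatoric(eps: np.ndarray) -> np.ndarray:
    e = eps.copy()
    tr3 = eps[:, :3].sum(axis=1) / 3.0
    e[:, :3] -= tr3[:, None]
    return e


def solve_transient(
    system: FESystem,
    load: LoadSpec,
    dt: float | None = None,
    n_cycles: int = 3,
    record: str = "membrane",
) -> StrainReport:
    """Step the viscoelastic system through the load history.

    For cyclic loads (frequency > 0) the default time step is period/40
    (dt must not exceed period/20) and the run covers ``n_cycles`` cycles;
    static loads run for ``load.duration`` (default 4 s, about 13
    relaxation times) at dt = 0.05 s.  Returns a :class:`StrainReport`
    with the strain history on the membrane layer (``record='membrane'``)
    or on every element (``record='all'``), with summary metrics evaluated
    at the cycle-maximum load of the final cycle (static: final step).
    """
    f = load.frequency
    if f > 0:
        period = 1.0 / f
        if dt is None:
            dt = period / 40.0
        if dt > period / 20.0 + 1e-12:
            raise ValueError("dt must be <= period/20 for cyclic loads")
        duration = load.duration if load.duration is not None else n_cycles * period
    else:
        if dt is None:
            dt = 0.05
        duration = load.duration if load.duration is not None else 4.0
    nt = max(2, int(round(duration / dt)))
    times = dt * np.arange(1, nt + 1)
    load_values = load.pressure(times)

    mesh = system.mesh
    if record == "membrane":
        rec_ids = mesh.membrane_elements
        if rec_ids.size == 0:
            raise ValueError("mesh has no membrane elements")
    else:
        rec_ids = np.arange(mesh.n_elements)

    K = system.effective_stiffness(dt)
    Kff = K[system.free][:, system.free]
    presc = system.prescribed_dofs
    Kfp = K[system.free][:, presc] if presc.size else None
    try:
        lu = splu(Kff.tocsc())
    except RuntimeError as e:
        raise SingularSystemError(f"stiffness factorisation failed: {e}") from e

    beta = np.exp(-dt / system.tau)
    gamma = (system.tau / dt) * (1.0 - beta)
    dG = system.G0 - system.G_inf

    ndof = system.ndof
    m = len(system.vol)
    h = np.zeros((m, 6))
    e_prev = np.zeros((m, 6))
    u = np.zeros(ndof)
    history = np.empty((nt, len(rec_ids), 6))

    for n in range(nt):
        shat = _VOIGT_W[None, :] * dG[:, None] * (
            beta[:, None] * h - gamma[:, None] * e_prev
        )
        fh = np.zeros(ndof)
        contrib = system.vol[:, None] * np.einsum("eij,ei->ej", system.B, shat)
        np.add.at(fh, system.dofmap.ravel(), contrib.ravel())
        rhs = load_values[n] * system.f_unit[system.free] - fh[system.free]
        u[:] = 0.0
        if presc.size:
            up = system.delta_per_pa * load_values[n] * system.prescribed_unit
            u[presc] = up
            rhs = rhs - Kfp @ up
        u[system.free] = lu.solve(rhs)
        eps = np.einsum("eij,ej->ei", system.B, u[system.dofmap])
        e_new = _deviatoric(eps)
        h = beta[:, None] * h + gamma[:, None] * (e_new - e_prev)
        e_prev = e_new
        history[n] = eps[rec_ids]

    areas = np.zeros(len(rec_ids))
    if len(mesh.membrane_faces):
        fa = mesh.face_areas(mesh.membrane_faces)
        pos = {int(e): i for i, e in enumerate(rec_ids)}
        for face_area, owner in zip(fa, mesh.membrane_owner):
            if int(owner) in pos:
                areas[pos[int(owner)]] += face_area

    cset = set(system.constrained_nodes.tolist())
    interior = np.array(
        [not (set(mesh.tets[e].tolist()) & cset) for e in rec_ids], dtype=bool
    )
    if not interior.any():
        interior = np.ones(len(rec_ids), dtype=bool)

    report = StrainReport(
        times=times, load_values=load_values, element_ids=rec_ids,
        strain_history=history, areas=areas, interior_mask=interior,
        frequency=f,
    )
    avg, peak, teval = membrane_principal_strain(report)
    report.avg_max_principal = avg
    report.peak_max_principal = peak
    report.evaluation_time = teval
    return report


def stress_history(system: FESystem, strain_history: np.ndarray,
                   dt: float) -> np.ndarray:
    """Per-element stress history from a full strain history.

    Applies the same exponential Prony recurrence used by the solver to a
    recorded ``(nt, m, 6)`` strain history on ALL elements (``record='all'``)
    and returns the ``(nt, m, 6)`` Voigt stresses (deviatoric viscoelastic
    part plus elastic volumetric part).  Truss forces are not included.
    """
    nt, m, _ = strain_history.shape
    beta = np.exp(-dt / system.tau)
    gamma = (system.tau / dt) * (1.0 - beta)
    dG = system.G0 - system.G_inf
    h = np.zeros((m, 6))
    e_prev = np.zeros((m, 6))
    out = np.empty_like(strain_history)
    for n in range(nt):
        eps = strain_history[n]
        e_new = _deviatoric(eps)
        h = beta[:, None] * h + gamma[:, None] * (e_new - e_prev)
        s = _VOIGT_W[None, :] * (system.G_inf[:, None] * e_new
                                 + dG[:, None] * h)
        p = system.K_bulk * eps[:, :3].sum(axis=1)
        out[n] = s + p[:, None] * _M[None, :]
        e_prev = e_new
    return out


def reaction_force(system: FESystem, stress: np.ndarray,
                   dofs: np.ndarray) -> float:
    """Sum of internal nodal forces at ``dofs`` for one stress state.

    For a displacement-controlled boundary this equals minus the reaction
    the support exerts; used to measure relaxation of the support force.
    """
    f_int = np.zeros(system.ndof)
    contrib = system.vol[:, None] * np.einsum("eij,ei->ej", system.B, stress)
    np.add.at(f_int, system.dofmap.ravel(), contrib.ravel())
    return float(f_int[np.asarray(dofs, dtype=int)].sum())


def membrane_principal_strain(report: StrainReport):
    """Area-weighted average and peak max principal strain at peak load.

    The evaluation instant is the recorded step with the largest applied
    load within the final cycle (for cyclic loads) or the final step (for
    static loads).  Elements touching a constrained node are excluded
    (boundary-condition dominated); elements without an apical face area
    fall back to uniform weights when no areas exist.  Returns
    ``(avg, peak, evaluation_time)``.
    """
    if report.strain_history.size == 0 or len(report.element_ids) == 0:
        raise ValueError("empty membrane element set")
    nt = len(report.times)
    if report.frequency > 0:
        period = 1.0 / report.frequency
        last = report.times > report.times[-1] - period + 1e-12
        idx = np.flatnonzero(last)
        n_eval = idx[np.argmax(report.load_values[idx])]
    else:
        n_eval = nt - 1
    mp = max_principal_strain(report.strain_history[n_eval])
    sel = report.interior_mask
    mp_s = mp[sel]
    w = report.areas[sel]
    if w.sum() <= 0:
        w = np.ones_like(mp_s)
    avg = float(np.average(mp_s, weights=w))
    peak = float(mp_s.max())
    return avg, peak, float(report.times[n_eval])
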