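"""Canonical-ensemble sampling of CG systems on tabulated potentials.

The Hamiltonian is assembled from tabulated bond/angle/torsion terms, the
tabulated short-range pair potentials (zero beyond the cutoff, exclusions
honoured), and a cutoff Coulomb term q_i q_j / (4 pi eps0 eps r) with a
uniform relative permittivity (default 78, emulating aqueous screening in
an implicit-solvent model).  Tables are evaluated through cubic splines so
the returned forces are the exact negative gradient of the energy.

Two samplers close the inverse-potential refinement loop:

* BAOAB Langevin dynamics (default; 10 fs step, 0.5 ps friction time) —
  generates the canonical distribution at the requested temperature;
* single-particle Metropolis Monte Carlo, useful for exactness checks on
  tiny systems.

All runs are reproducible bit-for-bit from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .mapping import CGTopology
from .potential_tables import PotentialTable
from .units import COULOMB_K, KB_KCAL, KB_KJ, KCAL_TO_KJ

__all__ = [
    "ThermoState",
    "CGSystem",
    "SamplerConfig",
    "Trajectory",
    "SamplerError",
    "evaluate_energy_forces",
    "minimize_energy",
    "sample_canonical",
    "kinetic_temperature",
    "random_configuration",
]


class SamplerError(RuntimeError):
    pass


@dataclass
class ThermoState:
    """Temperature (K) and the Boltzmann constant (kcal/(mol K))."""

    temperature: float = 303.0
    kB: float = KB_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return self.kB * self.temperature


@dataclass
class CGSystem:
    """A CG topology in a periodic orthorhombic box with its table set."""

    topology: CGTopology
    box: np.ndarray
    thermo: ThermoState = field(default_factory=ThermoState)
    epsilon: float = 78.0
    cutoff: float = 2.0
    tables: dict[str, PotentialTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.epsilon <= 0:
            raise ValueError("dielectric permittivity must be positive")
        if self.cutoff > self.box.min() / 2 + 1e-9:
            raise ValueError(
                f"cutoff {self.cutoff} nm exceeds half the minimum box "
                f"length {self.box.min() / 2:.3f} nm"
            )
        self._model: _EnergyModel | None = None

    def set_tables(self, tables: dict[str, PotentialTable]) -> None:
        self.tables = tables
        self._model = None

    def model(self) -> "_EnergyModel":
        if self._model is None:
            self._model = _EnergyModel(self)
        return self._model


@dataclass
class SamplerConfig:
    method: str = "langevin"  # langevin | metropolis
    timestep_fs: float = 10.0
    friction_ps: float = 0.5
    n_steps: int = 10000
    equil_steps: int = 0
    stride: int = 100
    seed: int = 0
    max_displacement: float = 0.05  # metropolis trial move half-width, nm

    def __post_init__(self) -> None:
        if self.n_steps < 0 or self.timestep_fs <= 0:
            raise ValueError("invalid sampler configuration")


@dataclass
class Trajectory:
    frames: np.ndarray  # (F, N, 3) nm
    box: np.ndarray  # (3,) nm
    energies: np.ndarray | None = None
    temperatures: np.ndarray | None = None
    final_positions: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _mi(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    return disp - np.round(disp / box) * box


class _TableEval:
    """Cubic-spline energy/force lookup with safe out-of-range behaviour."""

    def __init__(self, table: PotentialTable, clamp_right_zero: bool = False):
        self.spl = table.spline()
        self.dspl = self.spl.derivative()
        self.x0 = float(table.x[0])
        self.x1 = float(table.x[-1])
        self.u0 = float(self.spl(self.x0))
        self.du0 = float(self.dspl(self.x0))
        self.clamp = clamp_right_zero
        self.periodic = table.kind == "torsion"
        self.name = f"{table.kind}:{table.name}"

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        if self.periodic:
            x = self.x0 + (x - self.x0) % 360.0
            return self.spl(x), self.dspl(x)
        u = np.empty_like(x)
        du = np.empty_like(x)
        below = x < self.x0
        above = x > self.x1
        mid = ~(below | above)
        u[mid] = self.spl(x[mid])
        du[mid] = self.dspl(x[mid])
        # linear repulsive continuation below the table
        u[below] = self.u0 + self.du0 * (x[below] - self.x0)
        du[below] = self.du0
        if self.clamp:
            u[above] = 0.0
            du[above] = 0.0
        elif np.any(above):
            raise SamplerError(
                f"{self.name}: coordinate {x[above].max():.4f} beyond table "
                f"range [{self.x0:.4f}, {self.x1:.4f}]"
            )
        return u, du


class _EnergyModel:
    """Precompiled term lists and splines for one system + table set."""

    def __init__(self, system: CGSystem):
        top = system.topology
        self.box = system.box
        self.cutoff = system.cutoff
        n = top.n_beads

        def groups(terms, kind):
            by_type: dict[str, list] = {}
            for idx, t in terms:
                by_type.setdefault(t, []).append(idx)
            out = []
            for t, idxs in by_type.items():
                key = f"{kind}:{t}"
                if key not in system.tables:
                    raise SamplerError(f"missing table for {key}")
                out.append((np.array(idxs, dtype=int),
                            _TableEval(system.tables[key]), key))
            return out

        self.bonds = groups(top.terms.bonds, "bond")
        self.angles = groups(top.terms.angles, "angle")
        self.torsions = groups(top.terms.torsions, "torsion")

        # non-excluded pair list, grouped by pair type
        ii, jj = np.triu_indices(n, k=1)
        if top.exclusions:
            excl = np.array(sorted(top.exclusions), dtype=int)
            keys = ii.astype(np.int64) * n + jj
            ekeys = excl[:, 0].astype(np.int64) * n + excl[:, 1]
            keep = ~np.isin(keys, ekeys)
            ii, jj = ii[keep], jj[keep]
        from .mapping import canonical_type_name

        types = np.array(top.bead_types)
        pair_names = np.array([canonical_type_name((a, b))
                               for a, b in zip(types[ii], types[jj])])
        self.pairs = []
        for t in np.unique(pair_names):
            key = f"pair:{t}"
            if key not in system.tables:
                continue  # no short-range table for this pair type
            sel = pair_names == t
            self.pairs.append((ii[sel], jj[sel],
                               _TableEval(system.tables[key],
                                          clamp_right_zero=True), key))

        q = top.charges
        qq = q[ii] * q[jj]
        sel = np.abs(qq) > 0
        self.coul_all = (ii[sel], jj[sel], COULOMB_K * qq[sel] / system.epsilon)

        # Verlet neighbour list: pairs within list_radius = r_interact + skin
        # are kept; the list is rebuilt whenever any bead has moved more
        # than skin/2 since the last build, so no interacting pair is ever
        # missed between rebuilds.  Forces and energies are identical to
        # the full O(N^2) evaluation.
        table_reach = max((ev.x1 for _, _, ev, _ in self.pairs), default=0.0)
        self.list_radius = max(self.cutoff, table_reach) + 0.4
        self._ref_pos: np.ndarray | None = None
        self.pairs_active = self.pairs
        self.coul = self.coul_all

    def _maybe_rebuild(self, pos: np.ndarray) -> None:
        big = max(len(ii) for ii, *_ in self.pairs) if self.pairs else 0
        if big + len(self.coul_all[0]) < 5000:
            return  # small systems: the full pair list is cheap enough
        if self._ref_pos is not None:
            disp = _mi(pos - self._ref_pos, self.box)
            if float(np.abs(disp).max()) < 0.2:
                return
        self._ref_pos = pos.copy()
        active = []
        for ii, jj, ev, key in self.pairs:
            d = _mi(pos[jj] - pos[ii], self.box)
            keep = np.einsum("ij,ij->i", d, d) < self.list_radius ** 2
            active.append((ii[keep], jj[keep], ev, key))
        self.pairs_active = active
        ii, jj, kqq = self.coul_all
        d = _mi(pos[jj] - pos[ii], self.box)
        keep = np.einsum("ij,ij->i", d, d) < self.list_radius ** 2
        self.coul = (ii[keep], jj[keep], kqq[keep])

    def energy_forces(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        e, f, _ = self.energy_forces_terms(pos)
        return e, f

    def energy_forces_terms(self, pos: np.ndarray):
        self._maybe_rebuild(pos)
        n = pos.shape[0]
        F = np.zeros((n, 3))
        terms: dict[str, float] = {}
        box = self.box

        def scatter(idx, vec):
            for d in range(3):
                F[:, d] += np.bincount(idx, weights=vec[:, d], minlength=n)

        E = 0.0
        for idx, ev, key in self.bonds:
            d = _mi(pos[idx[:, 1]] - pos[idx[:, 0]], box)
            r = np.linalg.norm(d, axis=1)
            u, du = ev(r)
            E += u.sum()
            terms[key] = terms.get(key, 0.0) + float(u.sum())
            fv = (du / r)[:, None] * d  # force on i along +d
            scatter(idx[:, 0], fv)
            scatter(idx[:, 1], -fv)

        deg = 180.0 / np.pi
        for idx, ev, key in self.angles:
            u1 = _mi(pos[idx[:, 0]] - pos[idx[:, 1]], box)
            v1 = _mi(pos[idx[:, 2]] - pos[idx[:, 1]], box)
            nu = np.linalg.norm(u1, axis=1)
            nv = np.linalg.norm(v1, axis=1)
            uh = u1 / nu[:, None]
            vh = v1 / nv[:, None]
            c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
            theta = np.degrees(np.arccos(c))
            u, du = ev(theta)
            E += u.sum()
            terms[key] = terms.get(key, 0.0) + float(u.sum())
            dud = du * deg  # kcal/mol per radian
            gi = (c[:, None] * uh - vh) / (nu * s)[:, None]
            gk = (c[:, None] * vh - uh) / (nv * s)[:, None]
            scatter(idx[:, 0], -dud[:, None] * gi)
            scatter(idx[:, 2], -dud[:, None] * gk)
            scatter(idx[:, 1], dud[:, None] * (gi + gk))

        for idx, ev, key in self.torsions:
            b1 = _mi(pos[idx[:, 1]] - pos[idx[:, 0]], box)
            b2 = _mi(pos[idx[:, 2]] - pos[idx[:, 1]], box)
            b3 = _mi(pos[idx[:, 3]] - pos[idx[:, 2]], box)
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            b2h = b2 / nb2[:, None]
            x = np.einsum("ij,ij->i", n1, n2)
            y = np.einsum("ij,ij->i", np.cross(n1, n2), b2h)
            phi = np.degrees(np.arctan2(y, x))
            u, du = ev(phi)
            E += u.sum()
            terms[key] = terms.get(key, 0.0) + float(u.sum())
            dud = du * deg
            sn1 = np.einsum("ij,ij->i", n1, n1)
            sn2 = np.einsum("ij,ij->i", n2, n2)
            dphi1 = -(nb2 / sn1)[:, None] * n1
            dphi4 = (nb2 / sn2)[:, None] * n2
            c12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
            c32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
            dphi2 = (-1.0 - c12) * dphi1 + c32 * dphi4
            dphi3 = c12 * dphi1 + (-1.0 - c32) * dphi4
            scatter(idx[:, 0], -dud[:, None] * dphi1)
            scatter(idx[:, 1], -dud[:, None] * dphi2)
            scatter(idx[:, 2], -dud[:, None] * dphi3)
            scatter(idx[:, 3], -dud[:, None] * dphi4)

        for ii, jj, ev, key in self.pairs_active:
            d = _mi(pos[jj] - pos[ii], box)
            r = np.linalg.norm(d, axis=1)
            u, du = ev(r)
            E += u.sum()
            terms[key] = terms.get(key, 0.0) + float(u.sum())
            fv = (du / r)[:, None] * d
            scatter(ii, fv)
            scatter(jj, -fv)

        ii, jj, kqq = self.coul
        if len(ii):
            d = _mi(pos[jj] - pos[ii], box)
            r = np.linalg.norm(d, axis=1)
            inside = r < self.cutoff
            rin = r[inside]
            u = kqq[inside] / rin
            E += u.sum()
            terms["coulomb"] = float(u.sum())
            fv = (-kqq[inside] / rin ** 3)[:, None] * d[inside]
            scatter(ii[inside], fv)
            scatter(jj[inside], -fv)

        return float(E), F, terms


def evaluate_energy_forces(
    positions: np.ndarray, system: CGSystem
) -> tuple[float, np.ndarray]:
    """Total energy (kcal/mol) and per-bead forces (kcal/mol/nm)."""
    return system.model().energy_forces(np.asarray(positions, dtype=float))


def minimize_energy(
    positions: np.ndarray, system: CGSystem, maxiter: int = 500
) -> np.ndarray:
    """Local energy minimization (quasi-Newton) before sampling."""
    model = system.model()
    shape = positions.shape

    def fun(xf):
        # out-of-table trial configurations act as a barrier for the line
        # search rather than aborting the minimization
        try:
            e, f = model.energy_forces(xf.reshape(shape))
        except SamplerError:
            return 1e12, np.zeros_like(xf)
        return e, -f.ravel()

    res = minimize(fun, np.asarray(positions, dtype=float).ravel(), jac=True,
                   method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x.reshape(shape) % system.box


def kinetic_temperature(vel: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K) from velocities in nm/ps."""
    ke = 0.5 * float(np.sum(masses[:, None] * vel ** 2))  # amu nm^2/ps^2
    dof = 3 * vel.shape[0]
    return 2.0 * ke / (dof * KB_KJ)


def random_configuration(
    n: int, box: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    return rng.random((n, 3)) * np.asarray(box, dtype=float)


_EMAX_PER_BEAD = 1e6


def sample_canonical(
    system: CGSystem,
    config: SamplerConfig,
    initial: np.ndarray | None = None,
    minimize_first: bool = True,
) -> Trajectory:
    """Sample the canonical distribution of *system* at its thermostat T.

    If ``initial`` is None, beads start from a uniform random configuration
    relaxed by energy minimization.  Frames are recorded every ``stride``
    steps after ``equil_steps``.  Identical seeds give identical runs.
    """
    rng = np.random.default_rng(config.seed)
    top = system.topology
    n = top.n_beads
    pos = (np.array(initial, dtype=float) if initial is not None
           else random_configuration(n, system.box, rng))
    if pos.shape != (n, 3):
        raise SamplerError(f"initial positions shape {pos.shape} != ({n}, 3)")
    if minimize_first:
        pos = minimize_energy(pos, system)

    if config.method == "metropolis":
        return _metropolis(system, config, pos, rng)
    if config.method != "langevin":
        raise SamplerError(f"unknown sampling method {config.method!r}")

    model = system.model()
    m = top.masses
    T = system.thermo.temperature
    dt = config.timestep_fs * 1e-3  # ps
    gamma = 1.0 / config.friction_ps
    c1 = np.exp(-gamma * dt)
    sigma = np.sqrt(KB_KJ * T * (1.0 - c1 * c1) / m)[:, None]  # nm/ps

    vel = rng.normal(size=(n, 3)) * np.sqrt(KB_KJ * T / m)[:, None]
    e, F = model.energy_forces(pos)
    acc = KCAL_TO_KJ / m[:, None]  # kcal/mol/nm -> nm/ps^2 per unit force

    frames, energies, temps = [], [], []
    for step in range(config.n_steps):
        vel += 0.5 * dt * F * acc
        pos += 0.5 * dt * vel
        vel = c1 * vel + sigma * rng.normal(size=(n, 3))
        pos += 0.5 * dt * vel
        pos %= system.box
        e, F = model.energy_forces(pos)
        if not np.isfinite(e) or abs(e) > _EMAX_PER_BEAD * n:
            raise SamplerError(
                f"energy blow-up at step {step}: E = {e:.3e} kcal/mol "
                f"(max |F| = {np.abs(F).max():.3e})"
            )
        vel += 0.5 * dt * F * acc
        if step >= config.equil_steps and (step - config.equil_steps + 1) % config.stride == 0:
            frames.append(pos.copy())
            energies.append(e)
            temps.append(kinetic_temperature(vel, m))

    return Trajectory(
        frames=np.array(frames) if frames else np.empty((0, n, 3)),
        box=system.box.copy(),
        energies=np.array(energies),
        temperatures=np.array(temps),
        final_positions=pos.copy(),
    )


def _metropolis(
    system: CGSystem, config: SamplerConfig, pos: np.ndarray,
    rng: np.random.Generator,
) -> Trajectory:
    model = system.model()
    kT = system.thermo.kT
    n = pos.shape[0]
    e, _ = model.energy_forces(pos)
    frames, energies = [], []
    for step in range(config.n_steps):
        i = int(rng.integers(n))
        trial = pos.copy()
        trial[i] = (trial[i] + (rng.random(3) - 0.5) * 2 * config.max_displacement) % system.box
        try:
            et, _ = model.energy_forces(trial)
        except SamplerError:
            et = np.inf  # off-table trial: hard-wall rejection
        if et <= e or rng.random() < np.exp(-(et - e) / kT):
            pos, e = trial, et
        if step >= config.equil_steps and (step - config.equil_steps + 1) % config.stride == 0:
            frames.append(pos.copy())
            energies.append(e)
    return Trajectory(
        frames=np.array(frames) if frames else np.empty((0, n, 3)),
        box=system.box.copy(),
        energies=np.array(energies),
        final_positions=pos.copy(),
    )
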