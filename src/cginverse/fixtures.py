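"""Synthetic test inputs: a DOPE lipid, toy fluids, and ideal phases.

Everything here is generated programmatically and deterministically.

``make_dope_fixture`` builds an all-atom DOPE
(1,2-dioleoyl-sn-glycero-3-phosphoethanolamine, C41 H78 N O8 P, 129 atoms)
with element masses, a full chemical bond graph and fixture partial
charges, partitioned into 14 beads of the six types N (ethanolamine), P
(phosphate), CO (ester + glycerol fragment, twice), and per acyl chain
C3/C3/CdB/C3/C4.  The CG bond graph follows the standard 14-bead DOPE
model — the phosphate bead is bonded to both ester beads — which is a
modelling convention, not the literal chemistry, so it is passed
explicitly.  Atom partial charges are fixture conventions constrained to
plausible bead sums (+0.6 N, -0.8 P, +0.1 per CO, zero net charge).

``make_toy_fluid`` samples a one-type fluid from a known analytic pair
potential with the package's own canonical sampler, returning both the
trajectory and the generating potential tabulated on the standard grid —
the ground truth for potential-recovery experiments.

``make_ideal_bilayer`` / ``make_ideal_hexagonal`` place replicated
14-bead lipids in noiseless lamellar and inverted-hexagonal geometries for
testing the phase observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import (
    AtomisticTopology,
    Bead,
    CGTopology,
    MappingScheme,
    build_cg_topology,
    replicate_topology,
)
from .potential_tables import PotentialTable
from .sampler import (
    CGSystem,
    SamplerConfig,
    ThermoState,
    Trajectory,
    sample_canonical,
)
from .units import WATER_MOLAR_MASS

__all__ = [
    "ELEMENT_MASSES",
    "make_dope_fixture",
    "dope_molar_mass",
    "water_weight_percent",
    "ToyFluidSpec",
    "lj_potential",
    "make_toy_fluid",
    "make_ideal_bilayer",
    "make_ideal_hexagonal",
]

ELEMENT_MASSES = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.97376}

DOPE_CG_BONDS = [
    (0, 1),            # N - P
    (1, 2), (1, 3),    # P - CO (sn-1), P - CO (sn-2)
    (2, 4), (4, 5), (5, 6), (6, 7), (7, 8),      # chain 1: CO-C3-C3-CdB-C3-C4
    (3, 9), (9, 10), (10, 11), (11, 12), (12, 13),  # chain 2
]


def _build_dope_atoms():
    """Atom names, elements, charges, bonds, and the bead partition."""
    names: list[str] = []
    elements: list[str] = []
    charges: list[float] = []
    bonds: list[tuple[int, int]] = []
    beads: list[tuple[str, str, list[int]]] = []  # (bead name, type, atoms)

    def atom(name: str, element: str, q: float = 0.0) -> int:
        names.append(name)
        elements.append(element)
        charges.append(q)
        return len(names) - 1

    # --- ethanolamine head -> bead N (10 atoms, +0.60 e)
    iN = atom("N", "N", -0.30)
    hs = [atom(f"HN{i}", "H", 0.30) for i in (1, 2, 3)]
    c11 = atom("C11", "C")
    h11 = [atom("H11A", "H"), atom("H11B", "H")]
    c12 = atom("C12", "C")
    h12 = [atom("H12A", "H"), atom("H12B", "H")]
    bonds += [(iN, h) for h in hs] + [(iN, c11)]
    bonds += [(c11, h11[0]), (c11, h11[1]), (c11, c12), (c12, h12[0]), (c12, h12[1])]
    beads.append(("N", "N", [iN, *hs, c11, *h11, c12, *h12]))

    # --- phosphate -> bead P (5 atoms, -0.80 e)
    iP = atom("P", "P", 1.20)
    o11 = atom("O11", "O", -0.30)   # ester O to ethanolamine C12
    o12 = atom("O12", "O", -0.30)   # ester O to glycerol C3
    o13 = atom("O13", "O", -0.70)
    o14 = atom("O14", "O", -0.70)
    bonds += [(c12, o11), (o11, iP), (iP, o12), (iP, o13), (iP, o14)]
    beads.append(("P", "P", [iP, o11, o12, o13, o14]))

    # --- glycerol backbone (split across the two CO beads)
    c1 = atom("C1", "C", 0.30)
    h1 = [atom("H1A", "H", 0.05), atom("H1B", "H", 0.05)]
    c2 = atom("C2", "C", 0.25)
    h2 = atom("H2", "H", 0.05)
    c3 = atom("C3", "C", 0.20)
    h3 = [atom("H3A", "H"), atom("H3B", "H")]
    bonds += [(c1, h1[0]), (c1, h1[1]), (c1, c2), (c2, h2), (c2, c3),
              (c3, h3[0]), (c3, h3[1]), (c3, o12)]

    def ester(glycerol_c: int, label: str):
        o_link = atom(f"O{label}1", "O", -0.45)
        c_carb = atom(f"C{label}", "C", 0.70 if label == "31" else 0.60)
        o_carb = atom(f"O{label}2", "O", -0.55)
        bonds.extend([(glycerol_c, o_link), (o_link, c_carb), (c_carb, o_carb)])
        return o_link, c_carb, o_carb

    o31, c31, o32 = ester(c1, "31")
    o21, c21, o22 = ester(c2, "21")
    beads.append(("CO1", "CO", [c1, *h1, o31, c31, o32]))
    beads.append(("CO2", "CO", [c2, h2, c3, *h3, o21, c21, o22]))

    def oleoyl_chain(carbonyl: int, tag: str):
        """17 post-carbonyl carbons with a cis double bond at local 8-9."""
        catoms, prev = [], carbonyl
        for k in range(1, 18):
            c = atom(f"C{tag}{k}", "C")
            bonds.append((prev, c))
            prev = c
            if k == 17:
                nh = 3          # terminal methyl
            elif k in (8, 9):
                nh = 1          # double-bond carbons
            else:
                nh = 2
            hatoms = [atom(f"H{tag}{k}{chr(65 + j)}", "H") for j in range(nh)]
            for h in hatoms:
                bonds.append((c, h))
            catoms.append((c, hatoms))
        flat = lambda lo, hi: [a for c, hs_ in catoms[lo:hi] for a in (c, *hs_)]
        return [
            (f"C3{tag}a", "C3", flat(0, 4)),    # 4 C + 8 H
            (f"C3{tag}b", "C3", flat(4, 7)),    # 3 C + 6 H
            (f"CdB{tag}", "CdB", flat(7, 10)),  # 3 C + 4 H (double bond)
            (f"C3{tag}c", "C3", flat(10, 13)),  # 3 C + 6 H
            (f"C4{tag}", "C4", flat(13, 17)),   # 4 C + 9 H
        ]

    beads += oleoyl_chain(c31, "A")
    beads += oleoyl_chain(c21, "B")
    return names, elements, charges, bonds, beads


def make_dope_fixture() -> tuple[AtomisticTopology, MappingScheme, CGTopology]:
    """The 129-atom / 14-bead DOPE fixture: topology, scheme, CG topology."""
    names, elements, charges, bonds, bead_defs = _build_dope_atoms()
    topo = AtomisticTopology(
        names=names,
        masses=np.array([ELEMENT_MASSES[e] for e in elements]),
        charges=np.array(charges),
        bonds=bonds,
        species="DOPE",
    )
    scheme = MappingScheme(
        species="DOPE",
        beads=[Bead(n, t, tuple(a)) for n, t, a in bead_defs],
        type_alphabet=("N", "P", "CO", "C3", "CdB", "C4"),
        cg_bonds=DOPE_CG_BONDS,
    )
    cg = build_cg_topology(scheme, topo)
    return topo, scheme, cg


def dope_molar_mass() -> float:
    topo, _, _ = make_dope_fixture()
    return topo.molar_mass


def water_weight_percent(n_water: int, n_lipid: int,
                         lipid_molar_mass: float | None = None) -> float:
    """Water mass fraction (percent) of an n_water/n_lipid mixture."""
    if lipid_molar_mass is None:
        lipid_molar_mass = dope_molar_mass()
    mw = n_water * WATER_MOLAR_MASS
    return 100.0 * mw / (mw + n_lipid * lipid_molar_mass)


# ---------------------------------------------------------------------------
# toy fluids


@dataclass
class ToyFluidSpec:
    """A one-type fluid generated from a known analytic pair potential."""

    n_particles: int = 200
    box: tuple[float, float, float] = (3.5, 3.5, 3.5)
    temperature: float = 303.0
    epsilon: float = 0.3   # well depth, kcal/mol
    sigma: float = 0.4     # size parameter, nm
    cutoff: float = 1.2
    seed: int = 0
    mass: float = 72.0     # amu

    def __post_init__(self) -> None:
        if self.cutoff > min(self.box) / 2:
            raise ValueError("cutoff exceeds half the box")


def lj_potential(r: np.ndarray, epsilon: float, sigma: float,
                 cutoff: float) -> np.ndarray:
    """Truncated-and-shifted Lennard-Jones potential (kcal/mol)."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / np.maximum(r, 1e-6)) ** 6
    u = 4.0 * epsilon * (sr6 ** 2 - sr6)
    sc6 = (sigma / cutoff) ** 6
    u -= 4.0 * epsilon * (sc6 ** 2 - sc6)
    return np.where(r < cutoff, u, 0.0)


def toy_fluid_table(spec: ToyFluidSpec, spacing: float = 0.01,
                    u_cap: float = 50.0) -> PotentialTable:
    """The generating potential tabulated on the standard grid.

    The table starts where the repulsive wall reaches ``u_cap``; closer
    approaches are handled by the evaluator's linear (steeply repulsive)
    continuation, so the core never presents a zero-force plateau.
    """
    x = np.arange(spacing, spec.cutoff + 0.5 * spacing, spacing)
    x[-1] = spec.cutoff
    u = lj_potential(x, spec.epsilon, spec.sigma, spec.cutoff)
    start = int(np.argmax(u <= u_cap))
    return PotentialTable("pair", "A-A", x[start:], u[start:], cutoff=spec.cutoff)


def toy_fluid_system(spec: ToyFluidSpec,
                     table: PotentialTable | None = None) -> CGSystem:
    from .mapping import BondedTerms

    mol = CGTopology(
        bead_types=["A"],
        masses=np.array([spec.mass]),
        charges=np.array([0.0]),
        terms=BondedTerms(),
        exclusions=set(),
        molecule_ids=np.array([0]),
    )
    top = replicate_topology(mol, spec.n_particles)
    system = CGSystem(
        topology=top,
        box=np.array(spec.box),
        thermo=ThermoState(spec.temperature),
        cutoff=spec.cutoff,
    )
    system.set_tables({"pair:A-A": table if table is not None else toy_fluid_table(spec)})
    return system


def make_toy_fluid(
    spec: ToyFluidSpec,
    n_steps: int = 20000,
    equil_steps: int = 2000,
    stride: int = 10,
    timestep_fs: float = 10.0,
) -> tuple[Trajectory, PotentialTable, CGSystem]:
    """Sample the toy fluid canonically; returns (trajectory, truth, system)."""
    table = toy_fluid_table(spec)
    system = toy_fluid_system(spec, table)
    config = SamplerConfig(n_steps=n_steps, equil_steps=equil_steps,
                           stride=stride, seed=spec.seed,
                           timestep_fs=timestep_fs)
    traj = sample_canonical(system, config)
    return traj, table, system


# ---------------------------------------------------------------------------
# ideal phase geometries (14-bead lipid role template)

# per-bead (depth below the head plane, lateral offsets) for one lipid;
# order matches DOPE_CG_BONDS bead indices.  The small alternating dy
# zigzag keeps consecutive chain beads non-collinear so every torsion is
# geometrically well defined in the construction.
_LIPID_TEMPLATE = [
    # (depth, dx, dy)  with dx along the chain-splay direction
    ("N", 0.00, 0.25, 0.00),
    ("P", 0.00, 0.00, 0.00),
    ("CO1", 0.45, 0.15, 0.10),
    ("CO2", 0.45, -0.15, -0.10),
    ("C3Aa", 0.85, 0.15, 0.16),
    ("C3Ab", 1.25, 0.15, 0.04),
    ("CdBA", 1.55, 0.15, 0.16),
    ("C3Ac", 1.75, 0.15, 0.04),
    ("C4A", 1.90, 0.15, 0.16),
    ("C3Ba", 0.85, -0.15, -0.16),
    ("C3Bb", 1.25, -0.15, -0.04),
    ("CdBB", 1.55, -0.15, -0.16),
    ("C3Bc", 1.75, -0.15, -0.04),
    ("C4B", 1.90, -0.15, -0.16),
]


@dataclass
class IdealPhase:
    positions: np.ndarray
    box: np.ndarray
    topology: CGTopology
    n_lipids: int
    meta: dict = field(default_factory=dict)


def _dope_cg_molecule() -> CGTopology:
    _, _, cg = make_dope_fixture()
    return cg


def make_ideal_bilayer(
    n_lipids: int = 100,
    area_per_lipid: float = 0.6,
    thickness: float = 3.988,
    z_margin: float = 2.2,
    jitter: float = 0.0,
    seed: int = 0,
) -> IdealPhase:
    """A deterministic two-leaflet bilayer normal to z.

    Head (N, P) beads sit exactly at +-thickness/2; chains run inward.
    The lateral box area is n_lipids/2 * area_per_lipid.  Optional
    Gaussian ``jitter`` (nm) roughens the construction reproducibly.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two leaflets)")
    per_leaf = n_lipids // 2
    nx = int(np.ceil(np.sqrt(per_leaf)))
    ny = int(np.ceil(per_leaf / nx))
    area = per_leaf * area_per_lipid
    aspect = nx / ny
    lx = float(np.sqrt(area * aspect))
    ly = area / lx
    lz = thickness + 2 * z_margin
    box = np.array([lx, ly, lz])
    half = thickness / 2.0
    rng = np.random.default_rng(seed)

    mol = _dope_cg_molecule()
    pos = np.zeros((n_lipids * mol.n_beads, 3))
    k = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        count = 0
        for iy in range(ny):
            for ix in range(nx):
                if count >= per_leaf:
                    break
                # half-cell stagger keeps opposing tail ends off each other
                x0 = (ix + 0.5 + 0.5 * leaflet) * lx / nx
                y0 = (iy + 0.5 + 0.5 * leaflet) * ly / ny
                for _, depth, dx, dy in _LIPID_TEMPLATE:
                    z = lz / 2 + sign * (half - depth)
                    pos[k] = [x0 + dx, y0 + dy, z]
                    k += 1
                count += 1
    if jitter > 0:
        pos = pos + rng.normal(scale=jitter, size=pos.shape)
    pos %= box
    return IdealPhase(pos, box, replicate_topology(mol, n_lipids), n_lipids,
                      meta={"thickness": thickness, "area_per_lipid": area_per_lipid})


def make_ideal_hexagonal(
    spacing: float = 5.2,
    radius: float = 0.8,
    n_cols: int = 2,
    n_rows: int = 2,
    n_axial: int = 8,
    n_azimuthal: int = 12,
    axial_length: float = 5.0,
    splay_deg: float = 20.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> IdealPhase:
    """Inverted-hexagonal cylinders along x on a periodic hex lattice.

    Cylinder centres form a triangular lattice with nearest-neighbour
    distance ``spacing``; head (P) beads sit at ``radius`` from each axis
    (the implicit water core), chains point outward with an azimuthal
    splay that gives the wide cone angles characteristic of the phase.
    """
    box = np.array([axial_length, n_cols * spacing, n_rows * spacing * np.sqrt(3) / 2])
    centers = []
    for row in range(n_rows):
        for col in range(n_cols):
            y = (col + 0.5 * (row % 2)) * spacing
            z = row * spacing * np.sqrt(3) / 2
            centers.append((y, z))
    rng = np.random.default_rng(seed)
    mol = _dope_cg_molecule()
    n_lipids = len(centers) * n_axial * n_azimuthal
    pos = np.zeros((n_lipids * mol.n_beads, 3))
    splay = np.radians(splay_deg)
    k = 0
    for cy, cz in centers:
        for ia in range(n_axial):
            x0 = (ia + 0.5) * box[0] / n_axial
            for iphi in range(n_azimuthal):
                phi = 2 * np.pi * iphi / n_azimuthal
                for name, depth, dx, _ in _LIPID_TEMPLATE:
                    # radial distance grows with depth; chains splay in phi
                    r = radius + depth
                    sgn = np.sign(dx) if dx != 0 else 0.0
                    ang = phi + sgn * splay * (depth / 1.9)
                    pos[k] = [x0 + 0.2 * sgn, cy + r * np.cos(ang), cz + r * np.sin(ang)]
                    k += 1
    if jitter > 0:
        pos = pos + rng.normal(scale=jitter, size=pos.shape)
    pos %= box
    return IdealPhase(pos, box, replicate_topology(mol, n_lipids), n_lipids,
                      meta={"spacing": spacing, "radius": radius})


def synthetic_bilayer_tables(
    phase: IdealPhase,
    k_bond: float = 1000.0,      # kcal/mol/nm^2
    k_angle: float = 0.01,       # kcal/mol/deg^2
    k_torsion: float = 0.0005,   # kcal/mol/deg^2 (soft cosine-like well)
    lj_epsilon: float = 0.5,     # kcal/mol
    lj_sigma: float = 0.42,      # nm
    cutoff: float = 1.2,
) -> dict[str, PotentialTable]:
    """A synthetic stand-in potential set that holds a constructed phase.

    Bonded tables are harmonic restraints around the mean geometry of the
    construction's first molecule (each bond/angle/torsion type at its
    built-in value); non-bonded tables are a mildly cohesive truncated
    Lennard-Jones for every type pair.  This is *not* an inverted
    potential set — it exists so constructed phases can be thermalised by
    the canonical sampler and measured through the analysis pipeline.
    """
    from .distributions import angle_values, bond_lengths, torsion_values

    top = phase.topology
    first = top.molecule_ids == 0
    nb = int(first.sum())
    pos0 = phase.positions[:nb]
    bigbox = phase.box * 100  # construction geometry without imaging artefacts
    tables: dict[str, PotentialTable] = {}

    def mean_by_type(terms, func):
        vals: dict[str, list[float]] = {}
        for idx, t in terms:
            if max(idx) >= nb:
                continue
            v = func(pos0, bigbox, np.array([idx]))[0]
            vals.setdefault(t, []).append(float(v))
        return {t: float(np.mean(v)) for t, v in vals.items()}

    for t, r0 in mean_by_type(top.terms.bonds, bond_lengths).items():
        x = np.arange(0.02, 2.0 + 1e-9, 0.01)
        tables[f"bond:{t}"] = PotentialTable("bond", t, x, 0.5 * k_bond * (x - r0) ** 2)
    for t, a0 in mean_by_type(top.terms.angles, angle_values).items():
        x = np.arange(0.0, 180.0 + 1e-9, 2.0)
        tables[f"angle:{t}"] = PotentialTable("angle", t, x, 0.5 * k_angle * (x - a0) ** 2)
    for t, p0 in mean_by_type(top.terms.torsions, torsion_values).items():
        x = np.arange(-178.0, 180.0 + 1e-9, 4.0)
        d = (x - p0 + 180.0) % 360.0 - 180.0
        tables[f"torsion:{t}"] = PotentialTable("torsion", t, x, 0.5 * k_torsion * d ** 2)
    from .mapping import nonbonded_type_pairs

    xp = np.arange(0.01, cutoff + 1e-9, 0.01)
    u_lj = lj_potential(xp, lj_epsilon, lj_sigma, cutoff)
    start = int(np.argmax(u_lj <= 50.0))  # steep linear continuation below
    for t in nonbonded_type_pairs(top.bead_types):
        tables[f"pair:{t}"] = PotentialTable("pair", t, xp[start:].copy(),
                                             u_lj[start:].copy(), cutoff=cutoff)
    return tables
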