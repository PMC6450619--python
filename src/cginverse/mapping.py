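"""Atom-to-bead mapping and coarse-grained topology construction.

A mapping scheme partitions the atoms of one molecular species into beads.
Mapping a frame places each bead at the centre of mass of its atom group,
unwrapped by minimum image around the group's first atom so that groups
straddling a periodic boundary average correctly.  The CG bonded topology
(bonds, angles, torsions) is derived purely from the CG bond graph: angles
are all simple paths of length two, torsions all simple paths of length
three, with interaction type names canonicalised under reversal
(``N-P`` == ``P-N``).  Every bead pair that co-occurs in any bonded term is
excluded from non-bonded interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomisticTopology",
    "MappingScheme",
    "Bead",
    "BondedTerms",
    "CGTopology",
    "CGFrame",
    "MappingError",
    "validate_mapping",
    "map_frame",
    "aggregate_bead_charges",
    "canonical_type_name",
    "enumerate_bonded_terms",
    "nonbonded_type_pairs",
    "build_exclusions",
    "build_cg_topology",
    "replicate_topology",
]


class MappingError(ValueError):
    """Raised when a mapping scheme or topology violates its contract."""


@dataclass
class AtomisticTopology:
    """Atom names, masses (amu), partial charges (e) and molecular bonds."""

    names: list[str]
    masses: np.ndarray
    charges: np.ndarray
    bonds: list[tuple[int, int]]
    species: str = "molecule"

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.names)
        if self.masses.shape != (n,) or self.charges.shape != (n,):
            raise MappingError("names, masses and charges must have equal length")
        if np.any(self.masses <= 0):
            raise MappingError("atom masses must be strictly positive")
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise MappingError(f"bond ({i}, {j}) references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def molar_mass(self) -> float:
        return float(self.masses.sum())


@dataclass(frozen=True)
class Bead:
    """One CG site: a name, a type label, and its ordered member atoms."""

    name: str
    type: str
    atoms: tuple[int, ...]


@dataclass
class MappingScheme:
    """Partition of a molecule's atoms into beads, per species.

    ``cg_bonds`` optionally declares the CG bond graph explicitly, for
    models whose bead connectivity is a convention rather than the image
    of the chemical bond graph (bead indices refer to ``beads`` order).
    """

    species: str
    beads: list[Bead]
    type_alphabet: tuple[str, ...] = ()
    cg_bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.type_alphabet:
            self.type_alphabet = tuple(dict.fromkeys(b.type for b in self.beads))
        for b in self.beads:
            if len(b.atoms) == 0:
                raise MappingError(f"bead {b.name!r} has no atoms")
            if b.type not in self.type_alphabet:
                raise MappingError(
                    f"bead {b.name!r} has type {b.type!r} outside the alphabet "
                    f"{self.type_alphabet}"
                )

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class ValidationReport:
    species: str
    n_beads: int
    n_atoms: int
    ok: bool = True


def validate_mapping(scheme: MappingScheme, topo: AtomisticTopology) -> ValidationReport:
    """Check that *scheme* is a partition of the atoms of *topo*.

    Raises :class:`MappingError` naming the offending atoms/beads if an atom
    is assigned twice, left unassigned, or a bead is empty.
    """
    if scheme.species != topo.species:
        raise MappingError(
            f"scheme is for species {scheme.species!r}, topology for {topo.species!r}"
        )
    owner: dict[int, str] = {}
    for bead in scheme.beads:
        for a in bead.atoms:
            if not 0 <= a < topo.n_atoms:
                raise MappingError(f"bead {bead.name!r} references atom {a} "
                                   f"outside 0..{topo.n_atoms - 1}")
            if a in owner:
                raise MappingError(
                    f"atom {a} assigned to both beads {owner[a]!r} and {bead.name!r}"
                )
            owner[a] = bead.name
    orphans = sorted(set(range(topo.n_atoms)) - set(owner))
    if orphans:
        raise MappingError(f"atoms not assigned to any bead: {orphans}")
    return ValidationReport(scheme.species, scheme.n_beads, topo.n_atoms)


@dataclass
class CGFrame:
    """Bead positions (nm) with an orthorhombic periodic box (nm)."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise MappingError("box lengths must be strictly positive")
        if not np.all(np.isfinite(self.positions)):
            raise MappingError("positions must be finite")


def map_frame(
    positions: np.ndarray,
    box: np.ndarray,
    scheme: MappingScheme,
    topo: AtomisticTopology,
    time: float = 0.0,
) -> CGFrame:
    """Map an atomistic frame onto beads by centre of mass.

    Each atom group is unwrapped around its first atom by minimum image
    before mass-weighted averaging; the bead position is wrapped back into
    the box.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    if positions.shape != (topo.n_atoms, 3):
        raise MappingError(
            f"expected positions of shape ({topo.n_atoms}, 3), got {positions.shape}"
        )
    out = np.empty((scheme.n_beads, 3))
    for k, bead in enumerate(scheme.beads):
        idx = np.fromiter(bead.atoms, dtype=int)
        grp = positions[idx]
        m = topo.masses[idx]
        if m.sum() <= 0:
            raise MappingError(f"bead {bead.name!r} has zero total mass")
        ref = grp[0]
        disp = grp - ref
        disp -= np.round(disp / box) * box
        com = ref + (m[:, None] * disp).sum(axis=0) / m.sum()
        out[k] = com % box
    return CGFrame(out, box, time)


def aggregate_bead_charges(scheme: MappingScheme, topo: AtomisticTopology) -> np.ndarray:
    """Per-bead charge as the sum of member partial charges (e)."""
    return np.array([topo.charges[list(b.atoms)].sum() for b in scheme.beads])


def aggregate_bead_masses(scheme: MappingScheme, topo: AtomisticTopology) -> np.ndarray:
    return np.array([topo.masses[list(b.atoms)].sum() for b in scheme.beads])


def canonical_type_name(labels: tuple[str, ...] | list[str]) -> str:
    """Reversal-invariant interaction type name, e.g. ``P-N`` -> ``N-P``."""
    t = tuple(labels)
    return "-".join(min(t, t[::-1]))


@dataclass
class BondedTerms:
    """Bond/angle/torsion term index tuples with canonical type names."""

    bonds: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    angles: list[tuple[tuple[int, int, int], str]] = field(default_factory=list)
    torsions: list[tuple[tuple[int, int, int, int], str]] = field(default_factory=list)

    def type_counts(self) -> dict[str, int]:
        return {
            "bond": len({t for _, t in self.bonds}),
            "angle": len({t for _, t in self.angles}),
            "torsion": len({t for _, t in self.torsions}),
        }


def enumerate_bonded_terms(
    n_beads: int,
    cg_bonds: list[tuple[int, int]],
    bead_types: list[str],
) -> BondedTerms:
    """Enumerate bonded terms from the CG bond graph.

    Bonds are the graph edges, angles all paths of length two, torsions all
    simple paths of length three.  Each term and its type name are
    canonicalised under reversal so that e.g. A-B-B-A torsions traversed in
    either direction are the same term type.
    """
    adj: dict[int, set[int]] = {i: set() for i in range(n_beads)}
    for i, j in cg_bonds:
        adj[i].add(j)
        adj[j].add(i)

    terms = BondedTerms()
    for i, j in cg_bonds:
        idx = (i, j) if (i, j) <= (j, i) else (j, i)
        terms.bonds.append((idx, canonical_type_name((bead_types[idx[0]], bead_types[idx[1]]))))

    for j in range(n_beads):
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            idx = (i, j, k) if (i,) <= (k,) else (k, j, i)
            labels = tuple(bead_types[b] for b in idx)
            terms.angles.append((idx, canonical_type_name(labels)))

    seen: set[tuple[int, ...]] = set()
    for j, k in ((a, b) for a, b in cg_bonds):
        for j0, k0 in ((j, k), (k, j)):
            for i in adj[j0] - {k0}:
                for l in adj[k0] - {j0}:
                    if i == l:
                        continue  # 3-cycle, not a proper torsion path
                    path = (i, j0, k0, l)
                    canon = min(path, path[::-1])
                    if canon in seen:
                        continue
                    seen.add(canon)
                    labels = tuple(bead_types[b] for b in canon)
                    terms.torsions.append((canon, canonical_type_name(labels)))
    return terms


def nonbonded_type_pairs(bead_types: list[str] | tuple[str, ...]) -> list[str]:
    """All distinct unordered type pairs (n(n+1)/2 for n types)."""
    uniq = sorted(set(bead_types))
    return [canonical_type_name((a, b)) for a, b in
            itertools.combinations_with_replacement(uniq, 2)]


def build_exclusions(terms: BondedTerms) -> set[tuple[int, int]]:
    """Symmetric set of bead pairs co-occurring in any bonded term."""
    excl: set[tuple[int, int]] = set()
    groups = [idx for idx, _ in terms.bonds]
    groups += [idx for idx, _ in terms.angles]
    groups += [idx for idx, _ in terms.torsions]
    for grp in groups:
        for a, b in itertools.combinations(grp, 2):
            excl.add((min(a, b), max(a, b)))
    return excl


@dataclass
class CGTopology:
    """Beads (type/mass/charge), bonded terms, exclusions, molecule ids."""

    bead_types: list[str]
    masses: np.ndarray
    charges: np.ndarray
    terms: BondedTerms
    exclusions: set[tuple[int, int]]
    molecule_ids: np.ndarray
    bead_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if not self.bead_names:
            self.bead_names = [f"{t}{i}" for i, t in enumerate(self.bead_types)]

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    def interaction_type_counts(self) -> dict[str, int]:
        counts = self.terms.type_counts()
        counts["nonbonded"] = len(nonbonded_type_pairs(self.bead_types))
        return counts


def cg_bond_graph(scheme: MappingScheme, topo: AtomisticTopology) -> list[tuple[int, int]]:
    """CG bonds: bead pairs connected by at least one atomistic bond."""
    owner = {}
    for k, bead in enumerate(scheme.beads):
        for a in bead.atoms:
            owner[a] = k
    edges = set()
    for i, j in topo.bonds:
        bi, bj = owner[i], owner[j]
        if bi != bj:
            edges.add((min(bi, bj), max(bi, bj)))
    return sorted(edges)


def build_cg_topology(
    scheme: MappingScheme,
    topo: AtomisticTopology,
    cg_bonds: list[tuple[int, int]] | None = None,
) -> CGTopology:
    """Derive the full CG topology of one molecule from scheme + atomistics.

    By default CG bonds connect beads linked by at least one atomistic
    bond; an explicit ``cg_bonds`` graph overrides this when the CG model's
    connectivity is a modelling convention rather than a chemical one.
    """
    validate_mapping(scheme, topo)
    types = [b.type for b in scheme.beads]
    if cg_bonds is None:
        cg_bonds = (scheme.cg_bonds if scheme.cg_bonds is not None
                    else cg_bond_graph(scheme, topo))
    terms = enumerate_bonded_terms(scheme.n_beads, cg_bonds, types)
    return CGTopology(
        bead_types=types,
        masses=aggregate_bead_masses(scheme, topo),
        charges=aggregate_bead_charges(scheme, topo),
        terms=terms,
        exclusions=build_exclusions(terms),
        molecule_ids=np.zeros(scheme.n_beads, dtype=int),
        bead_names=[b.name for b in scheme.beads],
    )


def replicate_topology(mol: CGTopology, n_copies: int) -> CGTopology:
    """Tile a single-molecule topology into a system of ``n_copies`` molecules."""
    nb = mol.n_beads
    terms = BondedTerms()
    excl: set[tuple[int, int]] = set()
    for c in range(n_copies):
        off = c * nb
        for idx, t in mol.terms.bonds:
            terms.bonds.append((tuple(i + off for i in idx), t))
        for idx, t in mol.terms.angles:
            terms.angles.append((tuple(i + off for i in idx), t))
        for idx, t in mol.terms.torsions:
            terms.torsions.append((tuple(i + off for i in idx), t))
        for a, b in mol.exclusions:
            excl.add((a + off, b + off))
    return CGTopology(
        bead_types=mol.bead_types * n_copies,
        masses=np.tile(mol.masses, n_copies),
        charges=np.tile(mol.charges, n_copies),
        terms=terms,
        exclusions=excl,
        molecule_ids=np.repeat(np.arange(n_copies), nb),
        bead_names=[f"{name}.{c}" for c in range(n_copies) for name in mol.bead_names],
    )
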