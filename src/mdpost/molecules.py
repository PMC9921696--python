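"""Molecule detection and coarse-graining.

Free particles are mapped into molecules by a distance search on one
reference configuration: an edge joins two particles whose
minimum-image separation is below the bond cutoff for their species
pair, and connected components of the resulting graph are the
molecules.  The all-pairs search is O(N^2); mapping the fixed groups
over the trajectory is O(N).

Detected molecule graphs can be validated against a reference graph
built from a SMILES string (heavy atoms by default, since trajectories
often omit or constrain hydrogens): exact label-preserving isomorphism
first, then an approximate score from a graph-edit-distance bound.

The centre-of-mass trajectory of a molecule group is written back to
the store as a new species group, so every calculator applies to the
coarse-grained system unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import MDPostError
from .store import BoxMetadata, SpeciesRecord, TrajectoryStore
from .structural import minimum_image_displacements
from .transformations import ensure_unwrapped


@dataclass
class BondCutoffTable:
    """Symmetric (species, species) -> maximum bond length (m)."""

    cutoffs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for pair, c in list(self.cutoffs.items()):
            if c <= 0:
                raise ValueError(f"bond cutoff for {pair} must be positive")
            self.cutoffs[(pair[1], pair[0])] = c

    def get(self, a: str, b: str) -> float:
        return self.cutoffs.get((a, b), 0.0)

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoffs.values(), default=0.0)


@dataclass
class MoleculeGroup:
    """Molecules sharing one composition."""

    label: str
    member_indices: list[list[int]]  # global particle indices per molecule
    composition: dict[str, int]
    reference_graph: nx.Graph | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.member_indices)


def build_adjacency(
    positions: np.ndarray,
    species_of: list[str],
    cutoffs: BondCutoffTable,
    box: BoxMetadata,
) -> nx.Graph:
    """Distance-search bond graph of a single configuration.

    ``positions`` is (n_atoms, 3) for one frame in global particle-index
    order; ``species_of[i]`` labels atom i.  Edge (i, j) iff the
    minimum-image distance is within the cutoff for the species pair.
    """
    n = positions.shape[0]
    if cutoffs.max_cutoff >= min(box.edge_lengths) / 2:
        raise MDPostError("bond cutoffs must be below half the box edge")
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, species=species_of[i])
    d = minimum_image_displacements(positions, positions, box)
    dist = np.linalg.norm(d, axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            c = cutoffs.get(species_of[i], species_of[j])
            if c > 0 and dist[i, j] <= c:
                g.add_edge(i, j)
    return g


def decompose(graph: nx.Graph) -> list[MoleculeGroup]:
    """Connected components grouped by identical composition."""
    by_comp: dict[tuple, list[list[int]]] = {}
    for comp_nodes in nx.connected_components(graph):
        nodes = sorted(comp_nodes)
        comp: dict[str, int] = {}
        for n in nodes:
            sp = graph.nodes[n]["species"]
            comp[sp] = comp.get(sp, 0) + 1
        key = tuple(sorted(comp.items()))
        by_comp.setdefault(key, []).append(nodes)
    groups = []
    for key, members in sorted(by_comp.items()):
        comp = dict(key)
        label = "".join(f"{sp}{c if c > 1 else ''}" for sp, c in sorted(comp.items()))
        groups.append(MoleculeGroup(label=label, member_indices=sorted(members),
                                    composition=comp))
    return groups


def smiles_reference(smiles: str, include_hydrogens: bool = False) -> nx.Graph:
    """Element-labelled reference graph from a SMILES string.

    Heavy atoms only unless hydrogens are explicit in the SMILES and
    ``include_hydrogens`` is set.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MDPostError(f"unparsable SMILES {smiles!r}")
    if include_hydrogens:
        mol = Chem.AddHs(mol)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), species=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def _composition(graph: nx.Graph) -> dict[str, int]:
    comp: dict[str, int] = {}
    for _, data in graph.nodes(data=True):
        comp[data["species"]] = comp.get(data["species"], 0) + 1
    return comp


def check_isomorphism(
    molecule_graph: nx.Graph,
    reference_graph: nx.Graph,
    threshold: float = 0.95,
) -> tuple[bool, float, str]:
    """Label-preserving isomorphism check with an approximate fallback.

    Returns (match, score, diagnostic).  Exact isomorphism scores 1;
    otherwise the score is ``1 - GED_bound / max(|E|, |V|)`` using the
    first (fast) upper bound from networkx's graph-edit-distance
    optimisation, and the pair matches iff score >= threshold.
    A composition mismatch short-circuits to a mismatch before any
    search.
    """
    node_match = nx.algorithms.isomorphism.categorical_node_match("species", None)
    if _composition(molecule_graph) != _composition(reference_graph):
        return False, 0.0, "composition mismatch"
    if nx.is_isomorphic(molecule_graph, reference_graph, node_match=node_match):
        return True, 1.0, "exact isomorphism"
    bound = next(nx.optimize_graph_edit_distance(
        molecule_graph, reference_graph, node_match=node_match))
    denom = max(reference_graph.number_of_edges(),
                reference_graph.number_of_nodes(), 1)
    score = max(0.0, 1.0 - bound / denom)
    verdict = score >= threshold
    return verdict, score, f"edit-distance bound {bound:g}"


def make_whole(
    positions: np.ndarray,
    members: list[int],
    box: BoxMetadata,
) -> np.ndarray:
    """Shift molecule members to the periodic image nearest the first
    (anchor) member so the molecule is contiguous across boundaries.

    ``positions`` is (n_atoms, 3) global, one frame; returns the member
    coordinates (len(members), 3)."""
    anchor = positions[members[0]]
    out = positions[list(members)].copy()
    L = box.edges
    for ax in range(3):
        if box.periodic_flags[ax]:
            out[:, ax] -= L[ax] * np.round((out[:, ax] - anchor[ax]) / L[ax])
    return out


def com_trajectory(
    store: TrajectoryStore,
    group: MoleculeGroup,
    frame_range: tuple[int, int] | None = None,
    label: str | None = None,
) -> str:
    """Write the centre-of-mass trajectory of a molecule group as a new
    species group; returns its name.

    Membership is assumed constant over the range (no reactions).  COM
    positions are mass-weighted means of member *unwrapped* coordinates,
    anchored so molecules straddling the boundary are first made whole;
    COM velocities are mass-weighted mean member velocities.
    """
    label = label or f"mol_{group.label}"
    species = {sp.name: sp for sp in store.species_records}
    index_of: dict[int, tuple[str, int]] = {}
    for sp in species.values():
        for local, pid in enumerate(sp.particle_indices):
            index_of[pid] = (sp.name, local)

    unwrapped = {name: ensure_unwrapped(store, name) for name in species}
    velocities = {
        name: (store.load_property(name, "velocities")
               if store.has_property(name, "velocities") else None)
        for name in species
    }
    f0, f1 = frame_range if frame_range is not None else (0, store.n_frames)
    n_frames = f1 - f0
    n_mol = group.n_molecules
    com = np.zeros((n_mol, n_frames, 3))
    vel = np.zeros((n_mol, n_frames, 3))
    have_vel = all(v is not None for v in velocities.values())
    mol_mass = 0.0
    for m, members in enumerate(group.member_indices):
        masses = np.array([species[index_of[p][0]].mass for p in members])
        total = masses.sum()
        if m == 0:
            mol_mass = total
        # anchor on the first member's unwrapped path: shift each member by
        # the image offset that makes it whole relative to the anchor in the
        # first frame (offsets are constant for non-reactive molecules)
        sp0, loc0 = index_of[members[0]]
        anchor0 = unwrapped[sp0][loc0, f0, :]
        L = store.box.edges
        acc = np.zeros((n_frames, 3))
        vacc = np.zeros((n_frames, 3))
        for w, p in zip(masses, members):
            spn, loc = index_of[p]
            traj = unwrapped[spn][loc, f0:f1, :].astype(float)
            shift = np.zeros(3)
            for ax in range(3):
                if store.box.periodic_flags[ax]:
                    shift[ax] = -L[ax] * np.round((traj[0, ax] - anchor0[ax]) / L[ax])
            acc += w * (traj + shift)
            if have_vel:
                vacc += w * velocities[spn][loc, f0:f1, :]
        com[m] = acc / total
        if have_vel:
            vel[m] = vacc / total

    # register the COM group as a new species in the store
    h5 = store._h5
    if label in h5:
        del h5[label]
    g = h5.create_group(label)
    g.attrs["particle_indices"] = np.arange(n_mol, dtype=np.int64)
    g.attrs["mass"] = float(mol_mass)
    g.attrs["charge_number"] = 0
    g.attrs["mass_fraction"] = 0.0
    store.write_property(label, "unwrapped_positions", com)
    if have_vel:
        store.write_property(label, "velocities", vel)
    store.write_molecule_group(label, group.member_indices, group.composition)
    return label


def map_molecules(
    store: TrajectoryStore,
    cutoffs: BondCutoffTable,
    reference_frame: int = 0,
    check_frame: int | None = None,
    smiles: Mapping[str, str] | None = None,
) -> list[MoleculeGroup]:
    """Detect molecule groups on one reference configuration.

    ``check_frame`` optionally rebuilds the graph on a second frame and
    warns (via MDPostError message in the returned diagnostics) on
    membership changes.  ``smiles`` maps group labels to reference
    SMILES for isomorphism validation.
    """
    import warnings

    species = store.species_records
    n = store.n_atoms
    pos = np.zeros((n, 3))
    species_of = [""] * n
    for sp in species:
        p = store.load_property(sp.name, "positions",
                                frame_range=(reference_frame, reference_frame + 1))
        for local, pid in enumerate(sp.particle_indices):
            pos[pid] = p[local, 0, :]
            species_of[pid] = sp.name
    graph = build_adjacency(pos, species_of, cutoffs, store.box)
    groups = decompose(graph)

    if check_frame is not None:
        pos2 = np.zeros((n, 3))
        for sp in species:
            p = store.load_property(sp.name, "positions",
                                    frame_range=(check_frame, check_frame + 1))
            for local, pid in enumerate(sp.particle_indices):
                pos2[pid] = p[local, 0, :]
        groups2 = decompose(build_adjacency(pos2, species_of, cutoffs, store.box))
        if [g.member_indices for g in groups] != [g.member_indices for g in groups2]:
            warnings.warn("molecule membership differs between reference and "
                          "check frames; bonding may not be static")

    if smiles:
        for grp in groups:
            if grp.label in smiles:
                ref = smiles_reference(smiles[grp.label])
                grp.reference_graph = ref
                sub = graph.subgraph(grp.member_indices[0])
                relabel = nx.convert_node_labels_to_integers(sub)
                ok, score, diag = check_isomorphism(relabel, ref)
                if not ok:
                    raise MDPostError(
                        f"group {grp.label!r} does not match reference SMILES "
                        f"{smiles[grp.label]!r}: {diag} (score {score:.2f})"
                    )
    return groups
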