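"""Synthetic fixtures with analytically known answers.

Desk-scale stand-ins for the two expensive inputs of the real workflow:
molecular-dynamics conformer ensembles (emulated by uniform torsional
perturbation of a seed structure — plumbing, not thermodynamics) and the
large labeled descriptor dataset behind the logistic model (emulated by
Bernoulli draws from a known logistic curve). Every fixture is reproducible
bit-for-bit from its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import ConformerEnsemble, Molecule, normalized_masses

__all__ = [
    "FixtureSpec",
    "ChainFixture",
    "make_chain_molecule",
    "make_ring_molecule",
    "make_random_tree",
    "rotatable_bonds",
    "perturb_torsions",
    "simulate_amorphous_sampling",
    "simulate_labeled_dataset",
    "make_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible fixture: kind, size parameters, seed."""

    kind: str  # chain | ring | random_tree | torsion_ensemble | logistic_dataset
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class ChainFixture:
    """A collinear chain with closed-form leverages and R_k values."""

    molecule: Molecule
    leverages: np.ndarray       # x_i^2 / sum x^2
    r3_mass: float              # analytic R_3 with mass weights
    r3_unit: float              # analytic R_3 with unit weights


def _analytic_chain_r3(x: np.ndarray, w: np.ndarray) -> float:
    lev = x ** 2 / (x ** 2).sum()
    val = 0.0
    for i in range(len(x) - 3):
        j = i + 3
        val += np.sqrt(lev[i] * lev[j]) / abs(x[j] - x[i]) * w[i] * w[j]
    return float(val)


def make_chain_molecule(
    n_atoms: int, spacing: float = 1.0, elements=None, name: str = "chain"
) -> ChainFixture:
    """Centered collinear chain along x with analytic ground truth.

    The leverages of a collinear geometry reduce to x_i^2 / sum(x^2), which
    makes every R_k value available in closed form, independent of the
    production descriptor path.
    """
    if n_atoms < 2:
        raise ValueError("a chain needs at least two atoms")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if elements is None:
        elements = ["C"] * n_atoms
    if len(elements) != n_atoms:
        raise ValueError("element list length must equal n_atoms")
    x = spacing * (np.arange(n_atoms) - (n_atoms - 1) / 2.0)
    coords = np.zeros((n_atoms, 3))
    coords[:, 0] = x
    bonds = frozenset((i, i + 1) for i in range(n_atoms - 1))
    mol = Molecule(list(elements), coords, bonds, name)
    w = normalized_masses(elements)
    return ChainFixture(
        molecule=mol,
        leverages=x ** 2 / (x ** 2).sum(),
        r3_mass=_analytic_chain_r3(x, w),
        r3_unit=_analytic_chain_r3(x, np.ones(n_atoms)),
    )


def make_ring_molecule(
    n_atoms: int, bond_length: float = 1.5, elements=None, name: str = "ring"
) -> Molecule:
    """Planar regular n-ring in the xy plane (all leverages equal 2/n)."""
    if n_atoms < 3:
        raise ValueError("a ring needs at least three atoms")
    if elements is None:
        elements = ["C"] * n_atoms
    radius = bond_length / (2.0 * np.sin(np.pi / n_atoms))
    theta = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_atoms)]
    )
    bonds = frozenset(
        tuple(sorted((i, (i + 1) % n_atoms))) for i in range(n_atoms)
    )
    return Molecule(list(elements), coords, bonds, name)


def make_random_tree(
    n_atoms: int, seed: int = 0, elements=("C", "N", "O", "H"), name: str = "tree"
) -> Molecule:
    """Random tree-bonded molecule with random non-degenerate 3D coordinates.

    Each atom b attaches to a uniformly chosen earlier atom and is placed at
    a random direction 1.2-1.8 Angstrom away, so the bond graph is a uniform
    recursive tree and the geometry is generic (full-rank, no coincident
    atoms with overwhelming probability).
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    els = list(rng.choice(list(elements), size=n_atoms))
    coords = np.zeros((n_atoms, 3))
    bonds = set()
    for b in range(1, n_atoms):
        parent = int(rng.integers(0, b))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[b] = coords[parent] + rng.uniform(1.2, 1.8) * direction
        bonds.add((parent, b))
    return Molecule(els, coords, frozenset(bonds), name)


def _adjacency(n_atoms: int, bonds) -> list[set[int]]:
    adj = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _component(adj, start: int, blocked: frozenset) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if (u, v) in blocked or (v, u) in blocked or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def rotatable_bonds(molecule: Molecule) -> list[tuple[int, int, set[int]]]:
    """Non-ring, non-terminal bonds, with the atom set moved by a twist.

    A bond is rotatable when cutting it disconnects the graph (it is a
    bridge, hence not in a ring) and both sides contain at least two atoms.
    Returns (i, j, moving_side) triples where moving_side is the j-side.
    """
    adj = _adjacency(molecule.n_atoms, molecule.bonds)
    out = []
    for i, j in sorted(molecule.bonds):
        side_j = _component(adj, j, frozenset([(i, j)]))
        if i in side_j:  # bond is in a cycle
            continue
        side_i = set(range(molecule.n_atoms)) - side_j
        if len(side_i) < 2 or len(side_j) < 2:
            continue
        out.append((i, j, side_j))
    return out


def perturb_torsions(
    molecule: Molecule, n_conformers: int, max_twist: float, seed: int = 0
) -> ConformerEnsemble:
    """Torsion-perturbed conformer ensemble.

    Each conformer applies an independent uniform twist within +/- max_twist
    degrees about every rotatable bond, rigidly rotating one side, so bond
    lengths are preserved exactly. Deterministic under the seed.
    """
    rot_bonds = rotatable_bonds(molecule)
    if not rot_bonds:
        raise ValueError("molecule has no rotatable (non-ring, non-terminal) bond")
    if n_conformers < 1:
        raise ValueError("need at least one conformer")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_conformers):
        coords = molecule.coordinates.copy()
        for i, j, moving in rot_bonds:
            angle = rng.uniform(-max_twist, max_twist)
            axis = coords[j] - coords[i]
            norm = np.linalg.norm(axis)
            if norm == 0:
                raise ValueError(f"zero-length bond ({i},{j})")
            rot = Rotation.from_rotvec(np.radians(angle) * axis / norm)
            idx = sorted(moving - {j})
            if idx:
                coords[idx] = rot.apply(coords[idx] - coords[j]) + coords[j]
        frames.append(coords)
    return ConformerEnsemble(
        list(molecule.elements), molecule.bonds, frames,
        name=molecule.name,
        provenance=f"torsion perturbation +/-{max_twist} deg, seed {seed}",
    )


def simulate_amorphous_sampling(
    molecule: Molecule,
    n_cells: int = 3,
    n_frames: int = 7,
    n_molecules_per_cell: int = 40,
    max_twist: float = 60.0,
    seed: int = 0,
) -> ConformerEnsemble:
    """Emulate the amorphous-cell sampling bookkeeping.

    Triplicate independent cells, a fixed number of equally spaced frames
    per cell, every molecule extracted from every frame — one torsion-
    perturbed conformation each. Defaults mirror the study layout
    (3 cells x 7 frames x 40 molecules = 840 conformations per compound).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_cells):
        cell_seed = int(rng.integers(0, 2**31 - 1))
        sub = perturb_torsions(
            molecule, n_frames * n_molecules_per_cell, max_twist, seed=cell_seed
        )
        frames.extend(sub.frames)
    return ConformerEnsemble(
        list(molecule.elements), molecule.bonds, frames,
        name=molecule.name,
        provenance=(
            f"{n_cells} cells x {n_frames} frames x "
            f"{n_molecules_per_cell} molecules, seed {seed}"
        ),
    )


def simulate_labeled_dataset(
    beta0: float, beta1: float, n: int, x_range=(0.55, 0.72), seed: int = 0
):
    """Labeled descriptor sample from a known logistic curve.

    x ~ Uniform(x_range); label ~ Bernoulli(expit(beta0 + beta1 * x)).
    Returns (values, labels) as numpy arrays; deterministic under the seed.
    """
    if n < 2:
        raise ValueError("need at least two observations")
    lo, hi = x_range
    if not hi > lo:
        raise ValueError("x_range must be non-degenerate")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)
    from scipy.special import expit

    p = expit(beta0 + beta1 * x)
    labels = (rng.uniform(size=n) < p).astype(int)
    return x, labels


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its factory."""
    kind, p, seed = spec.kind, dict(spec.params), spec.seed
    if kind == "chain":
        return make_chain_molecule(**p)
    if kind == "ring":
        return make_ring_molecule(**p)
    if kind == "random_tree":
        return make_random_tree(seed=seed, **p)
    if kind == "torsion_ensemble":
        mol = p.pop("molecule")
        return perturb_torsions(mol, seed=seed, **p)
    if kind == "logistic_dataset":
        return simulate_labeled_dataset(seed=seed, **p)
    raise ValueError(f"unknown fixture kind {kind!r}")
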