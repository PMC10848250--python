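"""R-GETAWAY autocorrelation descriptors.

The R autocorrelation at topological lag k with atomic weights w is

    R_k(w) = sum_{i<j} [ sqrt(h_ii * h_jj) / r_ij ] * w_i * w_j * delta(k; d_ij)

where h_ii are the leverages (diagonal of the molecular influence matrix
H = M (M^T M)^- M^T built from the centered coordinate matrix M), r_ij is the
Euclidean interatomic distance, and d_ij the graph distance in bonds. R3m is
the k = 3, mass-weighted member — the descriptor driving the amorphous solid
dispersion formability model for PVPVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .structures import (
    Molecule,
    StructureError,
    center_coordinates,
    normalized_masses,
)

__all__ = [
    "InfluenceResult",
    "DescriptorResult",
    "DegenerateGeometryError",
    "CollinearTorsionError",
    "influence_matrix",
    "topological_distances",
    "r_autocorrelation",
    "r3m",
    "atom_contributions",
    "contribution_table",
    "dihedral",
]


class DegenerateGeometryError(ValueError):
    """Coincident atoms on a pair that should contribute to the descriptor."""


class CollinearTorsionError(ValueError):
    """Torsion undefined: three consecutive atoms are collinear."""


@dataclass(frozen=True)
class InfluenceResult:
    """Molecular influence (leverage) matrix and its diagonal."""

    leverages: np.ndarray  # h_ii, length A
    matrix: np.ndarray     # H, A x A


@dataclass(frozen=True)
class DescriptorResult:
    """An R_k(w) value with its per-atom decomposition."""

    value: float
    k: int
    weight_scheme: str
    per_atom: np.ndarray
    leverages: np.ndarray
    molecule_name: str = ""


def influence_matrix(centered: np.ndarray, rtol: float = 1e-6) -> InfluenceResult:
    """Leverage matrix H = M (M^T M)^- M^T of a centered coordinate matrix.

    The pseudo-inverse handles rank-deficient (planar or collinear)
    geometries; trace(H) then equals the coordinate rank (3, 2 or 1).

    Raises
    ------
    StructureError
        If the input is not centered (column means exceed ``rtol`` times the
        coordinate scale).
    """
    m = np.asarray(centered, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape[0] < 1:
        raise StructureError("expected a non-empty A x 3 coordinate matrix")
    scale = max(float(np.abs(m).max()), 1.0)
    if np.abs(m.mean(axis=0)).max() > rtol * scale:
        raise StructureError(
            "coordinates are not centered; call center_coordinates first"
        )
    h = m @ np.linalg.pinv(m.T @ m) @ m.T
    h = (h + h.T) / 2.0  # symmetrize away rounding noise
    return InfluenceResult(leverages=np.diag(h).copy(), matrix=h)


def topological_distances(bonds, n_atoms: int) -> np.ndarray:
    """All-pairs minimum bond-count distances (BFS per atom).

    Unreachable pairs (disconnected fragments) are ``inf``; the diagonal is 0.
    """
    rows, cols = [], []
    for i, j in bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_atoms, n_atoms)
    )
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def r_autocorrelation(
    molecule: Molecule, k: int = 3, weight_scheme: str = "mass"
) -> DescriptorResult:
    """R-GETAWAY autocorrelation R_k(w) of one conformation.

    The coordinates are centered internally before the leverage computation.
    Each contributing pair term is split half-and-half between its two atoms
    to form the per-atom decomposition, so the contributions sum to the value.

    Parameters
    ----------
    molecule
        Elements, coordinates and bond graph of one conformation.
    k
        Topological lag: only atom pairs exactly k bonds apart contribute.
    weight_scheme
        ``"mass"`` for atomic masses normalized to carbon, ``"unit"`` for
        unweighted.
    """
    if k < 1:
        raise ValueError("topological lag k must be a positive integer")
    a = molecule.n_atoms
    if a < 2:
        raise StructureError("descriptor requires at least two atoms")
    if weight_scheme == "mass":
        w = normalized_masses(molecule.elements)
    elif weight_scheme == "unit":
        w = np.ones(a)
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")

    coords = center_coordinates(molecule.coordinates)
    lev = influence_matrix(coords).leverages
    dtop = topological_distances(molecule.bonds, a)

    diff = coords[:, None, :] - coords[None, :, :]
    rij = np.sqrt((diff ** 2).sum(axis=-1))

    per_atom = np.zeros(a)
    value = 0.0
    ii, jj = np.nonzero(np.triu(dtop == k, 1))
    for i, j in zip(ii, jj):
        r = rij[i, j]
        if r == 0.0:
            raise DegenerateGeometryError(
                f"atoms {i} and {j} coincide but are {k} bonds apart"
            )
        term = np.sqrt(lev[i] * lev[j]) / r * w[i] * w[j]
        value += term
        per_atom[i] += term / 2.0
        per_atom[j] += term / 2.0
    return DescriptorResult(
        value=float(value), k=k, weight_scheme=weight_scheme,
        per_atom=per_atom, leverages=lev, molecule_name=molecule.name,
    )


def r3m(molecule: Molecule) -> DescriptorResult:
    """R3m: the mass-weighted R autocorrelation at lag 3."""
    return r_autocorrelation(molecule, k=3, weight_scheme="mass")


def atom_contributions(
    result: DescriptorResult, molecule: Molecule, selection: set[str]
) -> float:
    """Percentage of the descriptor value carried by the selected elements.

    A zero-valued descriptor is defined to contribute 0%.
    """
    sel = {s[0].upper() + s[1:].lower() for s in selection}
    if result.value == 0.0:
        return 0.0
    mask = np.array([e in sel for e in molecule.elements])
    return 100.0 * float(result.per_atom[mask].sum()) / result.value


def contribution_table(result: DescriptorResult, molecule: Molecule):
    """Per-atom contribution table (pandas DataFrame ready for CSV export)."""
    import pandas as pd

    total = result.value
    return pd.DataFrame(
        {
            "atom_index": np.arange(molecule.n_atoms),
            "element": molecule.elements,
            "leverage": result.leverages,
            "contribution": result.per_atom,
            "percent": (
                100.0 * result.per_atom / total
                if total != 0.0
                else np.zeros(molecule.n_atoms)
            ),
        }
    )


def dihedral(points: np.ndarray) -> float:
    """Signed torsion angle of four points about the 2-3 axis, degrees.

    Follows the standard atan2 construction; the result lies in (-180, 180].
    Raises :class:`CollinearTorsionError` when three consecutive points are
    collinear (the torsion is undefined).
    """
    p = np.asarray(points, dtype=float)
    if p.shape != (4, 3):
        raise ValueError("dihedral expects exactly four 3D points")
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    scale = max(
        np.linalg.norm(b1) * norm2, np.linalg.norm(b3) * norm2, 1e-300
    )
    if np.linalg.norm(n1) < 1e-10 * scale or np.linalg.norm(n2) < 1e-10 * scale:
        raise CollinearTorsionError("three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm2)
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)
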