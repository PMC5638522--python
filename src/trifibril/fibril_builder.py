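"""Construction of fibril simulation systems from a single template layer.

Covers the model-preparation arithmetic of a solvated amyloid fibril
study: stacking additional cross-beta layers along the mean inter-layer
displacement vector, N-terminal truncation with an acetyl (CH3-CO-) cap,
bookkeeping of atom counts / net charges / neutralizing counter ions, and
the periodic-box z-shrink that turns a finite stack into an infinite
fibril across the periodic boundary.

All counting assumes standard protonation at neutral pH: Asp/Glu
deprotonated (-1), Lys/Arg protonated (+1), His neutral, charged termini
contribute +1/-1.  This is the only convention that closes the solvated
system totals of a three-site water model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ArgumentError,
    CongruenceError,
    GeometryError,
    SequenceError,
    TopologyError,
)
from .structure_io import CHAIN_ALPHABET, FibrilModel

__all__ = [
    "ABETA40_SEQUENCE",
    "DisplacementVector",
    "CompositionReport",
    "BoxSpec",
    "mean_layer_displacement",
    "replicate_layers",
    "truncate_n_terminus",
    "count_chain_atoms",
    "net_chain_charge",
    "system_composition",
    "periodic_z_adjustment",
    "prune_waters_outside",
]

#: Amyloid-beta 1-40 primary sequence.
ABETA40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"

# Atoms per residue *inside* a peptide chain (backbone NH-CHR-CO plus side
# chain, hydrogens included) at standard protonation: Asp/Glu deprotonated,
# Lys/Arg protonated, His singly protonated (tautomer irrelevant to count).
_RESIDUE_ATOMS = {
    "G": 7, "A": 10, "S": 11, "C": 11, "T": 14, "V": 16, "L": 19, "I": 19,
    "M": 17, "P": 14, "F": 20, "Y": 21, "W": 24, "D": 12, "E": 15, "N": 14,
    "Q": 17, "K": 22, "R": 24, "H": 17,
}

_RESIDUE_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

#: atoms added by each terminus treatment
_N_TERM_ATOMS = {"charged": 2, "acetyl": 6}  # 2 extra H  /  CH3,C,O + 3 H
_C_TERM_ATOMS = {"charged": 1}               # extra carboxylate O

_N_TERM_CHARGE = {"charged": +1, "acetyl": 0}
_C_TERM_CHARGE = {"charged": -1}

#: cap internal geometry (Å); ideal values, no energies are ever computed
_CAP_C_N = 1.335
_CAP_C_O = 1.229
_CAP_C_CH3 = 1.510
_CAP_C_H = 1.090


@dataclass(frozen=True)
class DisplacementVector:
    """Mean displacement between adjacent fibril layers, Å."""

    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float).reshape(3))
        if not np.linalg.norm(self.v) > 0:
            raise ArgumentError("layer displacement vector must be non-zero")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.v))


@dataclass(frozen=True)
class CompositionReport:
    """Atom/charge/ion/water accounting of one solvated fibril system."""

    n_chains: int
    atoms_per_chain: int
    protein_atoms: int
    net_charge_per_chain: int
    n_counterions: int
    n_waters: int
    atoms_per_water: int
    total_atoms: int

    def __post_init__(self):
        expected = (self.protein_atoms + self.n_counterions
                    + self.atoms_per_water * self.n_waters)
        if expected != self.total_atoms:
            raise ArgumentError(
                f"composition identity violated: {expected} != {self.total_atoms}")


@dataclass(frozen=True)
class BoxSpec:
    """Simulation box; the infinite-fibril setup uses a cuboid."""

    shape: str
    dimensions: tuple

    def __post_init__(self):
        if self.shape not in ("cuboid", "truncated_octahedron"):
            raise ArgumentError(f"unknown box shape {self.shape!r}")
        if any(d <= 0 for d in self.dimensions):
            raise ArgumentError("box dimensions must be positive")

    @property
    def z_dimension(self) -> float:
        if self.shape != "cuboid":
            raise ArgumentError("z_dimension is defined for cuboid boxes only")
        return float(self.dimensions[2])


# ---------------------------------------------------------------------------
# Layer replication
# ---------------------------------------------------------------------------

def _chain_sort_order(model: FibrilModel, chain: str) -> np.ndarray:
    idx = model.atom_indices(chain_id=chain)
    key = np.lexsort((model.atom_name[idx], model.res_id[idx]))
    return idx[key]


def mean_layer_displacement(model: FibrilModel) -> DisplacementVector:
    """Average displacement from each layer to the one above it.

    Averaged over all filaments, all adjacent layer pairs, and all atoms
    matched by (residue number, atom name) between the two chains.
    """
    if model.topology is None or model.n_layers < 2:
        raise ArgumentError("a topology map with at least 2 layers is required")
    deltas = []
    for f in range(1, model.n_filaments + 1):
        chains = model.filament_chains(f)
        for lower, upper in zip(chains[:-1], chains[1:]):
            ilo = _chain_sort_order(model, lower)
            ihi = _chain_sort_order(model, upper)
            if (len(ilo) != len(ihi)
                    or np.any(model.res_id[ilo] != model.res_id[ihi])
                    or np.any(model.atom_name[ilo] != model.atom_name[ihi])):
                raise CongruenceError(
                    f"chains {lower!r} and {upper!r} of filament {f} do not "
                    "share a matched atom list")
            deltas.append(model.coord[ihi] - model.coord[ilo])
    return DisplacementVector(np.concatenate(deltas).mean(axis=0))


def replicate_layers(template_layer: FibrilModel, v: DisplacementVector,
                     n_layers: int) -> FibrilModel:
    """Stack *n_layers* copies of a single template layer along *v*.

    Layer k atoms are the template atoms translated by (k-1)·v; stacking is
    exactly in register (no twist).  Fresh single-character chain ids are
    assigned layer-major and the topology map is set.
    """
    if n_layers < 1:
        raise ArgumentError("n_layers must be >= 1")
    if template_layer.topology is not None and template_layer.n_layers != 1:
        raise ArgumentError("template must contain exactly one layer")
    chains = template_layer.chain_ids()
    n_fil = len(chains)
    if n_fil * n_layers > len(CHAIN_ALPHABET):
        raise ArgumentError(
            f"{n_fil * n_layers} chains exceed the available chain ids")

    cols = {"serial": [], "atom_name": [], "res_name": [], "res_id": [],
            "chain_id": [], "coord": [], "element": []}
    topo = {}
    serial_offset = 0
    for layer in range(1, n_layers + 1):
        shift = (layer - 1) * v.v
        for fil, chain in enumerate(chains, start=1):
            idx = template_layer.atom_indices(chain_id=chain)
            new_id = CHAIN_ALPHABET[(layer - 1) * n_fil + (fil - 1)]
            topo[new_id] = (fil, layer)
            cols["serial"].append(np.arange(serial_offset + 1,
                                            serial_offset + 1 + len(idx)))
            serial_offset += len(idx)
            cols["atom_name"].append(template_layer.atom_name[idx])
            cols["res_name"].append(template_layer.res_name[idx])
            cols["res_id"].append(template_layer.res_id[idx])
            cols["chain_id"].append(np.full(len(idx), new_id, dtype="U4"))
            cols["coord"].append(template_layer.coord[idx] + shift)
            cols["element"].append(template_layer.element[idx])
    return FibrilModel(
        np.concatenate(cols["serial"]), np.concatenate(cols["atom_name"]),
        np.concatenate(cols["res_name"]), np.concatenate(cols["res_id"]),
        np.concatenate(cols["chain_id"]), np.concatenate(cols["coord"]),
        np.concatenate(cols["element"]), topo, n_fil, n_layers)


# ---------------------------------------------------------------------------
# N-terminal truncation with acetyl capping
# ---------------------------------------------------------------------------

def _orthonormal_to(d: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to *d*."""
    basis = np.eye(3)
    e = basis[np.argmin(np.abs(d))]
    u = np.cross(d, e)
    return u / np.linalg.norm(u)


def _cap_atoms(anchor: np.ndarray, direction: np.ndarray):
    """Coordinates and names of the six acetyl-cap atoms.

    *anchor* is the new N-terminal nitrogen (or Cα in coarse models);
    *direction* points away from the chain along the former backbone.
    The cap is built with ideal internal geometry; since no energy is
    computed only chemical sanity is required.
    """
    d = direction / np.linalg.norm(direction)
    u = _orthonormal_to(d)
    c = anchor + _CAP_C_N * d
    o = c + _CAP_C_O * (np.cos(np.radians(60)) * d + np.sin(np.radians(60)) * u)
    ch3 = c + _CAP_C_CH3 * (np.cos(np.radians(60)) * d - np.sin(np.radians(60)) * u)
    axis = (ch3 - c) / np.linalg.norm(ch3 - c)
    perp = _orthonormal_to(axis)
    perp2 = np.cross(axis, perp)
    hs = []
    for k in range(3):
        ang = 2 * np.pi * k / 3
        hdir = (np.cos(np.radians(109.5)) * (-axis)
                + np.sin(np.radians(109.5)) * (np.cos(ang) * perp + np.sin(ang) * perp2))
        hs.append(ch3 + _CAP_C_H * -hdir)
    names = ["CH3", "C", "O", "HH31", "HH32", "HH33"]
    elements = ["C", "C", "O", "H", "H", "H"]
    coords = [ch3, c, o] + hs
    return names, elements, coords


def truncate_n_terminus(model: FibrilModel,
                        first_kept_residue: int = 9) -> FibrilModel:
    """Remove residues < *first_kept_residue* and acetyl-cap every chain.

    The cap (residue name ``ACE``, six atoms: CH3, C, O and three methyl
    hydrogens) is placed along the former backbone direction, bonded to the
    new N-terminal nitrogen.  Applying the operation twice is a no-op on
    the residue range.
    """
    cols = {k: [] for k in ("serial", "atom_name", "res_name", "res_id",
                            "chain_id", "coord", "element")}
    serial = 0
    for chain in model.chain_ids():
        cidx = model.atom_indices(chain_id=chain)
        res_ids = model.res_id[cidx]
        already_capped = np.any(model.res_name[cidx] == "ACE")
        kept = cidx[(res_ids >= first_kept_residue)
                    | (model.res_name[cidx] == "ACE")]
        if len(kept) == 0:
            raise ArgumentError(
                f"chain {chain!r} has no residues >= {first_kept_residue}")
        if not already_capped:
            anchor_i = _anchor_atom(model, chain, first_kept_residue)
            direction = _cap_direction(model, chain, first_kept_residue, anchor_i)
            names, elements, coords = _cap_atoms(model.coord[anchor_i], direction)
            for nm, el, xyz in zip(names, elements, coords):
                serial += 1
                cols["serial"].append(serial)
                cols["atom_name"].append(nm)
                cols["res_name"].append("ACE")
                cols["res_id"].append(first_kept_residue - 1)
                cols["chain_id"].append(chain)
                cols["coord"].append(xyz)
                cols["element"].append(el)
        for i in kept:
            serial += 1
            cols["serial"].append(serial)
            cols["atom_name"].append(model.atom_name[i])
            cols["res_name"].append(model.res_name[i])
            cols["res_id"].append(model.res_id[i])
            cols["chain_id"].append(model.chain_id[i])
            cols["coord"].append(model.coord[i])
            cols["element"].append(model.element[i])
    return FibrilModel(cols["serial"], cols["atom_name"], cols["res_name"],
                       cols["res_id"], cols["chain_id"],
                       np.array(cols["coord"]), cols["element"],
                       model.topology, model.n_filaments, model.n_layers)


def _anchor_atom(model, chain, first_kept, _names=("N", "CA")):
    for name in _names:
        idx = model.atom_indices(chain_id=chain, res_id=first_kept,
                                 atom_name=name)
        if len(idx):
            return int(idx[0])
    raise ArgumentError(
        f"chain {chain!r} residue {first_kept} lacks an N/CA anchor atom")


def _cap_direction(model, chain, first_kept, anchor_i):
    # prefer the direction towards the removed residue's Cα (the former
    # backbone continuation); fall back to extrapolating the kept chain
    prev = model.atom_indices(chain_id=chain, res_id=first_kept - 1,
                              atom_name="CA")
    if len(prev):
        d = model.coord[int(prev[0])] - model.coord[anchor_i]
    else:
        nxt = model.atom_indices(chain_id=chain, res_id=first_kept + 1,
                                 atom_name=model.atom_name[anchor_i])
        if len(nxt):
            d = model.coord[anchor_i] - model.coord[int(nxt[0])]
        else:
            d = np.array([1.0, 0.0, 0.0])
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Sequence-based atom and charge bookkeeping
# ---------------------------------------------------------------------------

def _check_sequence(sequence: str):
    bad = set(sequence.upper()) - set(_RESIDUE_ATOMS)
    if bad or not sequence:
        raise SequenceError(
            f"unknown residue letters {sorted(bad)!r}" if bad
            else "empty sequence")


def count_chain_atoms(sequence: str, n_terminus: str = "charged",
                      c_terminus: str = "charged") -> int:
    """Total atom count (hydrogens included) of one peptide chain.

    Standard protonation at neutral pH.  A charged N-terminus adds two
    protons, a charged C-terminus one carboxylate oxygen; an acetyl
    N-terminus adds the six cap atoms and no terminal proton.
    """
    _check_sequence(sequence)
    if n_terminus not in _N_TERM_ATOMS:
        raise ArgumentError(f"unsupported N-terminus {n_terminus!r}")
    if c_terminus not in _C_TERM_ATOMS:
        raise ArgumentError(f"unsupported C-terminus {c_terminus!r}")
    core = sum(_RESIDUE_ATOMS[a] for a in sequence.upper())
    return core + _N_TERM_ATOMS[n_terminus] + _C_TERM_ATOMS[c_terminus]


def net_chain_charge(sequence: str, n_terminus: str = "charged",
                     c_terminus: str = "charged") -> int:
    """Net charge of one chain in elementary charges (His neutral)."""
    _check_sequence(sequence)
    if n_terminus not in _N_TERM_CHARGE:
        raise ArgumentError(f"unsupported N-terminus {n_terminus!r}")
    if c_terminus not in _C_TERM_CHARGE:
        raise ArgumentError(f"unsupported C-terminus {c_terminus!r}")
    side = sum(_RESIDUE_CHARGE.get(a, 0) for a in sequence.upper())
    return side + _N_TERM_CHARGE[n_terminus] + _C_TERM_CHARGE[c_terminus]


def system_composition(n_filaments: int, n_layers: int, sequence: str,
                       n_terminus: str = "charged", n_waters: int = 0,
                       atoms_per_water: int = 3) -> CompositionReport:
    """Full atom accounting of one solvated, Na+-neutralized system.

    ``n_layers`` is the number of layers in the periodic cell (an infinite
    fibril with 12 layers per cell passes 12).  The water count is an
    input: solvation is performed by an external engine, only its result
    is book-kept.
    """
    if n_waters < 0:
        raise ArgumentError("n_waters must be >= 0")
    n_chains = n_filaments * n_layers
    per_chain = count_chain_atoms(sequence, n_terminus)
    charge = net_chain_charge(sequence, n_terminus)
    total_charge = n_chains * charge
    if total_charge > 0:
        raise ArgumentError(
            "net positive protein charge: only Na+ counter ions are supported")
    n_ions = -total_charge
    protein = n_chains * per_chain
    return CompositionReport(
        n_chains=n_chains, atoms_per_chain=per_chain, protein_atoms=protein,
        net_charge_per_chain=charge, n_counterions=n_ions, n_waters=n_waters,
        atoms_per_water=atoms_per_water,
        total_atoms=protein + n_ions + atoms_per_water * n_waters)


# ---------------------------------------------------------------------------
# Infinite-fibril periodic box adjustment
# ---------------------------------------------------------------------------

def periodic_z_adjustment(model: FibrilModel, box: BoxSpec,
                          template_spacing: float,
                          reference: str = "ca_centroid"):
    """Shrink the cuboid z dimension so the periodic image continues the fibril.

    The fibril axis must be aligned with z.  The distance along z between
    the top layer and the periodic image of the bottom layer is measured
    on matched reference atoms (default: Cα centroids of the terminal
    layers); the box is shrunk by the excess over *template_spacing* so
    that the image spacing equals the template's layer spacing exactly.

    Returns ``(new_z, shrink)``.  Idempotent: re-running on the adjusted
    box yields shrink 0.
    """
    if box.shape != "cuboid":
        raise ArgumentError("periodic z adjustment requires a cuboid box")
    if model.topology is None:
        raise ArgumentError("model needs a topology map")
    if reference != "ca_centroid":
        raise ArgumentError(f"unknown reference selection {reference!r}")

    def _layer_z(layer):
        zs = []
        for f in range(1, model.n_filaments + 1):
            chain = model.chain_of(f, layer)
            idx = model.atom_indices(chain_id=chain, atom_name="CA")
            if len(idx) == 0:
                raise GeometryError(
                    f"chain {chain!r} has no CA reference atoms")
            zs.append(model.coord[idx, 2].mean())
        return float(np.mean(zs))

    z_bottom = _layer_z(1)
    z_top = _layer_z(model.n_layers)
    extent = z_top - z_bottom
    if box.z_dimension <= extent:
        raise GeometryError(
            f"box z dimension {box.z_dimension:.2f} Å does not contain the "
            f"fibril extent {extent:.2f} Å")
    d_img = box.z_dimension - extent
    shrink = d_img - template_spacing
    new_z = box.z_dimension - shrink
    if shrink >= box.z_dimension:
        raise GeometryError("required shrink exceeds the box z dimension")
    if new_z <= extent:
        raise GeometryError(
            f"adjusted z dimension {new_z:.2f} Å is smaller than the fibril "
            f"extent {extent:.2f} Å")
    return float(new_z), float(shrink)


def prune_waters_outside(waters, box: BoxSpec):
    """Drop waters whose oxygen z lies outside the half-open [0, z) slab.

    The half-open interval avoids counting a molecule on the periodic face
    twice.  Returns ``(kept, n_deleted)`` with input order preserved.
    """
    z_max = box.z_dimension
    waters = [np.asarray(w, dtype=float) for w in waters]
    kept = [w for w in waters if 0.0 <= w[2] < z_max]
    return kept, len(waters) - len(kept)
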