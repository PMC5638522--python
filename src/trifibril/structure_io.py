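"""Reading, writing and indexing of fibril structures and coordinate frames.

The central container is :class:`FibrilModel`: a flat atom table plus a
*topology map* assigning every chain to a ``(filament, layer)`` cell of the
F x L fibril grid.  Filaments are the protofilament stacks (three in a
fibril with C3 symmetry), layers the ~4.8 Å cross-beta slices.  All
analysis modules index structures exclusively through this map, so the
chain-order convention used to build it is explicit and overridable.

PDB input/output is delegated to :mod:`biotite`; the test surface uses
plain (multi-model) PDB text only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ArgumentError,
    CongruenceError,
    EmptyStructureError,
    StructureFormatError,
    StructureParseError,
    TopologyError,
)

__all__ = [
    "AtomRecord",
    "FibrilModel",
    "TrajectoryFrames",
    "read_structure",
    "read_frames",
    "write_structure",
    "write_frames",
    "assign_topology",
]

#: chain identifiers handed out when replicating layers (PDB single-char field)
CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a fibril model, PDB-style annotation."""

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    element: str
    is_hydrogen: bool


class FibrilModel:
    """Atom table plus chain -> (filament, layer) topology map.

    Columns are numpy arrays of equal length; ``coord`` is float64 in Å.
    The topology map is ``None`` until :func:`assign_topology` is applied.
    Filament and layer indices are 1-based.
    """

    def __init__(self, serial, atom_name, res_name, res_id, chain_id,
                 coord, element, topology=None, n_filaments=0, n_layers=0):
        self.serial = np.asarray(serial, dtype=int)
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.res_name = np.asarray(res_name, dtype="U4")
        self.res_id = np.asarray(res_id, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.coord = np.asarray(coord, dtype=np.float64).reshape(-1, 3)
        self.element = np.asarray(element, dtype="U2")
        self.topology = dict(topology) if topology else None
        self.n_filaments = n_filaments
        self.n_layers = n_layers
        if not np.all(np.isfinite(self.coord)):
            raise ArgumentError("atom positions must be finite")
        n = len(self.coord)
        for col in (self.serial, self.atom_name, self.res_name,
                    self.res_id, self.chain_id, self.element):
            if len(col) != n:
                raise ArgumentError("atom table columns have unequal length")

    # -- basic properties -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.element) == "H"

    def chain_ids(self) -> list[str]:
        """Chain identifiers in first-occurrence (deposition) order."""
        seen, order = set(), []
        for c in self.chain_id:
            if c not in seen:
                seen.add(c)
                order.append(str(c))
        return order

    def chain_of(self, filament: int, layer: int) -> str:
        """Chain id occupying grid cell ``(filament, layer)``."""
        self._require_topology()
        for cid, (f, l) in self.topology.items():
            if f == filament and l == layer:
                return cid
        raise TopologyError(f"no chain assigned to filament {filament}, layer {layer}")

    def filament_chains(self, filament: int) -> list[str]:
        """Chain ids of one filament ordered bottom layer to top layer."""
        self._require_topology()
        pairs = sorted((l, c) for c, (f, l) in self.topology.items() if f == filament)
        if not pairs:
            raise TopologyError(f"no chains assigned to filament {filament}")
        return [c for _, c in pairs]

    def _require_topology(self):
        if self.topology is None:
            raise TopologyError("model has no topology map; call assign_topology first")

    # -- selection --------------------------------------------------------

    def atom_indices(self, chain_id=None, res_id=None, res_range=None,
                     atom_name=None, heavy_only=False) -> np.ndarray:
        """Indices of atoms matching all given criteria (AND semantics)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            chains = [chain_id] if isinstance(chain_id, str) else list(chain_id)
            mask &= np.isin(self.chain_id, chains)
        if res_id is not None:
            ids = [res_id] if np.isscalar(res_id) else list(res_id)
            mask &= np.isin(self.res_id, ids)
        if res_range is not None:
            lo, hi = res_range
            mask &= (self.res_id >= lo) & (self.res_id <= hi)
        if atom_name is not None:
            names = [atom_name] if isinstance(atom_name, str) else list(atom_name)
            mask &= np.isin(self.atom_name, names)
        if heavy_only:
            mask &= ~self.is_hydrogen
        return np.flatnonzero(mask)

    # -- construction helpers --------------------------------------------

    def with_coords(self, coord: np.ndarray) -> "FibrilModel":
        """Copy of the model carrying new coordinates (same atom table)."""
        coord = np.asarray(coord, dtype=np.float64)
        if coord.shape != self.coord.shape:
            raise CongruenceError(
                f"coordinate array shape {coord.shape} does not match "
                f"model with {self.n_atoms} atoms")
        return FibrilModel(self.serial, self.atom_name, self.res_name,
                           self.res_id, self.chain_id, coord, self.element,
                           self.topology, self.n_filaments, self.n_layers)

    def subset(self, indices: np.ndarray, keep_topology=True) -> "FibrilModel":
        idx = np.asarray(indices, dtype=int)
        return FibrilModel(
            self.serial[idx], self.atom_name[idx], self.res_name[idx],
            self.res_id[idx], self.chain_id[idx], self.coord[idx],
            self.element[idx],
            self.topology if keep_topology else None,
            self.n_filaments if keep_topology else 0,
            self.n_layers if keep_topology else 0)

    def atom_records(self):
        """Iterate over atoms as :class:`AtomRecord` objects."""
        hyd = self.is_hydrogen
        for i in range(self.n_atoms):
            yield AtomRecord(int(self.serial[i]), str(self.atom_name[i]),
                             str(self.res_name[i]), int(self.res_id[i]),
                             str(self.chain_id[i]), self.coord[i].copy(),
                             str(self.element[i]), bool(hyd[i]))

    def __repr__(self):
        topo = (f"{self.n_filaments}x{self.n_layers}"
                if self.topology is not None else "unassigned")
        return f"<FibrilModel {self.n_atoms} atoms, {len(self.chain_ids())} chains, topology {topo}>"


@dataclass
class TrajectoryFrames:
    """Ordered coordinate frames congruent with one model's atom list.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``times`` are frame
    times in ns (synthetic 0, 1, 2, ... when the source provides none).
    """

    coords: np.ndarray
    times: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ArgumentError("frames must have shape (n_frames, n_atoms, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ArgumentError("one time per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ArgumentError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __iter__(self):
        return iter(self.coords)


# ---------------------------------------------------------------------------
# PDB text input
# ---------------------------------------------------------------------------

def _validate_atom_lines(pdb_text: str) -> int:
    """Pre-scan ATOM/HETATM records; return their count.

    Raises :class:`StructureParseError` naming the first malformed line,
    which biotite's own error message would not.
    """
    n = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise StructureParseError(
                f"line {lineno}: ATOM record too short: {line!r}")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise StructureParseError(
                f"line {lineno}: malformed ATOM record fields: {line!r}") from exc
    return n


def _model_atom_counts(pdb_text: str) -> list[int]:
    """Atom counts per MODEL block (single pseudo-block if no MODEL card)."""
    counts, current, in_model, seen_model = [], 0, False, False
    for line in pdb_text.splitlines():
        if line.startswith("MODEL"):
            seen_model, in_model, current = True, True, 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            current += 1
            if not seen_model:
                in_model = True
    if not seen_model:
        counts = [current]
    elif in_model:          # trailing MODEL without ENDMDL
        counts.append(current)
    return counts


def _from_atom_array(array: struc.AtomArray) -> FibrilModel:
    serial = np.arange(1, array.array_length() + 1)
    if "atom_id" in array.get_annotation_categories():
        serial = array.atom_id.astype(int)
    return FibrilModel(serial, array.atom_name, array.res_name,
                       array.res_id, array.chain_id,
                       array.coord.astype(np.float64), array.element)


def read_structure(pdb_text: str) -> FibrilModel:
    """Parse PDB text into a :class:`FibrilModel` (topology unassigned).

    When the file holds several models, model 1 is used as the structure
    (the convention for NMR ensembles used as modelling templates).
    """
    if _validate_atom_lines(pdb_text) == 0:
        raise EmptyStructureError("input contains no ATOM records")
    pdb = PDBFile.read(io.StringIO(pdb_text))
    try:
        array = pdb.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # pragma: no cover - biotite internals
        raise StructureParseError(f"could not parse PDB text: {exc}") from exc
    return _from_atom_array(array)


def read_frames(multi_model_pdb_text: str, model: FibrilModel) -> TrajectoryFrames:
    """Read every MODEL block of a multi-model PDB as one trajectory frame.

    Each block must be atom-congruent with *model*; frame times are the
    synthetic sequence 0, 1, 2, ... ns.
    """
    if _validate_atom_lines(multi_model_pdb_text) == 0:
        raise EmptyStructureError("input contains no ATOM records")
    counts = _model_atom_counts(multi_model_pdb_text)
    for i, c in enumerate(counts, start=1):
        if c != model.n_atoms:
            raise CongruenceError(
                f"MODEL {i} has {c} atoms, expected {model.n_atoms}")
    pdb = PDBFile.read(io.StringIO(multi_model_pdb_text))
    coords = pdb.get_coord(model=None).astype(np.float64)
    return TrajectoryFrames(coords)


# ---------------------------------------------------------------------------
# PDB text output
# ---------------------------------------------------------------------------

def _to_atom_array(model: FibrilModel, coord=None) -> struc.AtomArray:
    for cid in model.chain_ids():
        if len(cid) > 1:
            raise StructureFormatError(
                f"chain id {cid!r} does not fit the 1-character PDB field")
    n = model.n_atoms
    array = struc.AtomArray(n)
    array.coord = (model.coord if coord is None else coord).astype(np.float32)
    array.chain_id = model.chain_id
    array.res_id = model.res_id
    array.res_name = model.res_name
    array.atom_name = model.atom_name
    array.element = model.element
    array.hetero = np.isin(model.res_name, list(_WATER_NAMES))
    return array


def write_structure(model: FibrilModel) -> str:
    """Serialize a model as PDB text (ATOM records, 3-decimal coordinates)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model))
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


def write_frames(frames: TrajectoryFrames, model: FibrilModel) -> str:
    """Serialize trajectory frames as multi-model PDB text."""
    if frames.n_atoms != model.n_atoms:
        raise CongruenceError(
            f"frames carry {frames.n_atoms} atoms, model has {model.n_atoms}")
    template = _to_atom_array(model)
    stack = struc.stack([template] * frames.n_frames)
    stack.coord = frames.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Topology assignment
# ---------------------------------------------------------------------------

def assign_topology(model: FibrilModel, n_filaments: int, n_layers: int,
                    chain_order: str = "layer_major",
                    mapping: dict | None = None) -> FibrilModel:
    """Return a copy of *model* with a bijective chain -> (f, l) map.

    ``chain_order="layer_major"`` assigns chains in deposition order to
    layer 1 filaments 1..F, then layer 2, ...; ``"filament_major"`` fills
    filament 1 layers 1..L first.  An explicit *mapping* (chain id ->
    (filament, layer)) overrides the convention.
    """
    if n_filaments < 1 or n_layers < 1:
        raise ArgumentError("n_filaments and n_layers must be >= 1")
    chains = model.chain_ids()
    expected = n_filaments * n_layers
    if len(chains) != expected:
        raise TopologyError(
            f"expected {expected} chains for a {n_filaments}x{n_layers} grid, "
            f"found {len(chains)}")
    if mapping is not None:
        topo = {str(c): (int(f), int(l)) for c, (f, l) in mapping.items()}
    elif chain_order == "layer_major":
        topo = {c: (i % n_filaments + 1, i // n_filaments + 1)
                for i, c in enumerate(chains)}
    elif chain_order == "filament_major":
        topo = {c: (i // n_layers + 1, i % n_layers + 1)
                for i, c in enumerate(chains)}
    else:
        raise ArgumentError(f"unknown chain_order convention {chain_order!r}")
    _check_bijection(topo, set(chains), n_filaments, n_layers)
    return FibrilModel(model.serial, model.atom_name, model.res_name,
                       model.res_id, model.chain_id, model.coord,
                       model.element, topo, n_filaments, n_layers)


def _check_bijection(topo, chains, n_filaments, n_layers):
    if set(topo) != chains:
        raise TopologyError("topology map chains do not match model chains")
    cells = set(topo.values())
    grid = {(f, l) for f in range(1, n_filaments + 1)
            for l in range(1, n_layers + 1)}
    if cells != grid or len(cells) != len(topo):
        raise TopologyError(
            "topology map is not a bijection onto the filament x layer grid")
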