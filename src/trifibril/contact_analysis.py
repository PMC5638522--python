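"""Atom-pair contact statistics for fibril trajectories.

A *contact* is an atom pair from two disjoint selections at a distance
strictly below a cutoff (4 Å by default; boundary equality counts as no
contact, which keeps repeated runs bit-reproducible).  Built on this
criterion are:

* the N-terminus x turn contact-frequency map (residues 1–8 of each
  chain against residues 21–30 of its cyclic intra-layer successor,
  1→2, 2→3, 3→1), reported as the percentage of frames a residue pair
  has at least one atom pair in contact, averaged over all layers and,
  when several trajectories are supplied, over runs;
* per-chain-pair contact kymographs ordered as the panels of a stacked
  fibril plot (pair blocks 1↔2, 2↔3, 3↔1, layers bottom to top);
* per-frame inter-filament atom-pair counts for the three filament
  interfaces, optionally normalized per layer.

Neighbor search uses a k-d tree; tests hold it to an O(n²) brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ArgumentError, SelectionError, TopologyError
from .structure_io import FibrilModel, TrajectoryFrames

__all__ = [
    "ContactDefinition",
    "ContactMap",
    "ContactSeries",
    "atom_pair_contacts",
    "residue_contact_fraction",
    "contact_map",
    "contact_kymograph",
    "interfilament_series",
    "FILAMENT_PAIRS",
]

#: the three interfaces of a three-filament fibril, in reporting order
FILAMENT_PAIRS = ((1, 2), (2, 3), (3, 1))


@dataclass(frozen=True)
class ContactDefinition:
    """Distance criterion for atom-pair contacts."""

    cutoff: float = 4.0
    include_hydrogens: bool = True
    atom_scope: str = "all"  # "all" | "heavy"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ArgumentError("contact cutoff must be positive")
        if self.atom_scope not in ("all", "heavy"):
            raise ArgumentError(f"unknown atom_scope {self.atom_scope!r}")

    @property
    def keep_hydrogens(self) -> bool:
        return self.include_hydrogens and self.atom_scope == "all"


@dataclass(frozen=True)
class ContactMap:
    """Residue-pair contact frequencies in percent, rows x cols."""

    rows: tuple
    cols: tuple
    values: np.ndarray  # shape (len(rows), len(cols)), 0..100
    row_names: tuple = ()
    col_names: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 100):
            raise ArgumentError("contact percentages must lie in [0, 100]")
        object.__setattr__(self, "values", v)

    def value(self, res_row: int, res_col: int) -> float:
        return float(self.values[self.rows.index(res_row),
                                 self.cols.index(res_col)])


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame inter-filament atom-pair counts and their sum."""

    pairs: tuple            # filament index pairs, e.g. ((1,2),(2,3),(3,1))
    counts: np.ndarray      # shape (n_frames, n_pairs)
    total: np.ndarray       # shape (n_frames,)
    normalization: str      # "raw" | "per_layer"
    times: np.ndarray = field(default=None)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if np.any(counts < 0):
            raise ArgumentError("contact counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", np.asarray(self.total, dtype=float))
        if not np.allclose(self.total, counts.sum(axis=1)):
            raise ArgumentError("total must equal the sum over filament pairs")


def _filter_scope(model: FibrilModel, idx: np.ndarray,
                  cd: ContactDefinition) -> np.ndarray:
    if cd.keep_hydrogens:
        return idx
    return idx[~model.is_hydrogen[idx]]


def atom_pair_contacts(frame: np.ndarray, selection_a, selection_b,
                       cd: ContactDefinition = ContactDefinition()) -> int:
    """Number of atom pairs (a in A, b in B) with distance < cutoff.

    Selections are atom index arrays and must be disjoint.
    """
    ia = np.asarray(selection_a, dtype=int)
    ib = np.asarray(selection_b, dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        raise SelectionError("contact selections must be non-empty")
    if len(np.intersect1d(ia, ib)) > 0:
        raise SelectionError("contact selections overlap")
    return _count_contacts(frame[ia], frame[ib], cd.cutoff)


def _count_contacts(coords_a: np.ndarray, coords_b: np.ndarray,
                    cutoff: float) -> int:
    """Strict (< cutoff) pair count via k-d tree with exact re-check."""
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    # tree query is inclusive (<=); re-check distances for the strict rule
    n = 0
    for i, neighbors in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        if neighbors:
            d = np.linalg.norm(coords_b[neighbors] - coords_a[i], axis=1)
            n += int(np.sum(d < cutoff))
    return n


def _min_distance(coords_a, coords_b) -> float:
    tree = cKDTree(coords_b)
    d, _ = tree.query(coords_a, k=1)
    return float(np.min(d))


# ---------------------------------------------------------------------------
# Chain-pair rules
# ---------------------------------------------------------------------------

def _intra_layer_successor_pairs(model: FibrilModel):
    """(chain, successor, layer) triples under the cyclic 1→2, 2→3, 3→1 rule."""
    model._require_topology()
    out = []
    for layer in range(1, model.n_layers + 1):
        for f in range(1, model.n_filaments + 1):
            succ = f % model.n_filaments + 1
            out.append((model.chain_of(f, layer),
                        model.chain_of(succ, layer), layer, (f, succ)))
    return out


def _residue_atoms(model, chain, res, cd):
    idx = model.atom_indices(chain_id=chain, res_id=res)
    idx = _filter_scope(model, idx, cd)
    if len(idx) == 0:
        raise SelectionError(
            f"residue {res} missing from chain {chain!r}")
    return idx


# ---------------------------------------------------------------------------
# Residue contact fractions and the N-terminus x turn map
# ---------------------------------------------------------------------------

def residue_contact_fraction(frames, model: FibrilModel, res_a: int,
                             res_b: int,
                             cd: ContactDefinition = ContactDefinition(),
                             chain_pair_rule: str = "intra_layer_successor",
                             ) -> float:
    """Percentage of frames with residue *res_a* (chain) touching *res_b*
    (successor chain), averaged over all intra-layer neighbor chain pairs.

    *frames* may be one :class:`TrajectoryFrames` or a list of them (runs);
    several runs are averaged with equal weight.
    """
    runs = frames if isinstance(frames, (list, tuple)) else [frames]
    if chain_pair_rule != "intra_layer_successor":
        raise ArgumentError(f"unknown chain-pair rule {chain_pair_rule!r}")
    pairs = _intra_layer_successor_pairs(model)
    per_run = []
    for run in runs:
        fractions = []
        for chain, succ, _, _ in pairs:
            ia = _residue_atoms(model, chain, res_a, cd)
            ib = _residue_atoms(model, succ, res_b, cd)
            hits = sum(_min_distance(f[ia], f[ib]) < cd.cutoff for f in run)
            fractions.append(hits / run.n_frames)
        per_run.append(100.0 * np.mean(fractions))
    return float(np.mean(per_run))


def contact_map(frames, model: FibrilModel, rows=range(1, 9),
                cols=range(21, 31),
                cd: ContactDefinition = ContactDefinition()) -> ContactMap:
    """Contact-frequency matrix of N-terminal vs turn residues.

    Rows default to the N-terminal arm (1–8), columns to the turn region
    (21–30) of the cyclic successor chain within the same layer.  Values
    are mean percentages over frames, layers and runs.
    """
    rows, cols = tuple(rows), tuple(cols)
    runs = frames if isinstance(frames, (list, tuple)) else [frames]
    try:
        for chain in model.chain_ids():
            for r in rows:
                _residue_atoms(model, chain, r, cd)
    except SelectionError as exc:
        raise SelectionError(
            f"cannot build the map: {exc} (truncated input has no "
            f"N-terminal residues)") from exc

    pairs = _intra_layer_successor_pairs(model)
    values = np.zeros((len(rows), len(cols)))
    for i, ra in enumerate(rows):
        for j, rb in enumerate(cols):
            per_run = []
            for run in runs:
                fr = []
                for chain, succ, _, _ in pairs:
                    ia = _residue_atoms(model, chain, ra, cd)
                    ib = _residue_atoms(model, succ, rb, cd)
                    hits = sum(_min_distance(f[ia], f[ib]) < cd.cutoff
                               for f in run)
                    fr.append(hits / run.n_frames)
                per_run.append(np.mean(fr))
            values[i, j] = 100.0 * np.mean(per_run)
    row_names = tuple(_res_label(model, r) for r in rows)
    col_names = tuple(_res_label(model, r) for r in cols)
    return ContactMap(rows, cols, values, row_names, col_names)


def _res_label(model, res_id):
    idx = model.atom_indices(res_id=res_id)
    name = str(model.res_name[idx[0]]) if len(idx) else "UNK"
    return f"{name}{res_id}"


def contact_kymograph(frames: TrajectoryFrames, model: FibrilModel,
                      res_a: int, res_b: int,
                      cd: ContactDefinition = ContactDefinition(),
                      value: str = "min_distance"):
    """Per-chain-pair time series of one residue contact.

    Returns ``(matrix, labels)`` with 3·L rows: the 1↔2 interface for
    layers 1..L (bottom to top), then 2↔3, then 3↔1 — row 3L is the 3↔1
    pair in the top layer.  ``value`` is the minimum atom distance or a
    contact boolean per frame.
    """
    if value not in ("min_distance", "bool"):
        raise ArgumentError(f"unknown value mode {value!r}")
    pairs = _intra_layer_successor_pairs(model)
    # reorder pair-major: all layers of 1->2, then 2->3, then 3->1
    ordered = [p for want in FILAMENT_PAIRS for p in pairs if p[3] == want]
    matrix = np.empty((len(ordered), frames.n_frames))
    labels = []
    for r, (chain, succ, layer, (f, s)) in enumerate(ordered):
        ia = _residue_atoms(model, chain, res_a, cd)
        ib = _residue_atoms(model, succ, res_b, cd)
        for t, frame in enumerate(frames):
            d = _min_distance(frame[ia], frame[ib])
            matrix[r, t] = (d < cd.cutoff) if value == "bool" else d
        labels.append(f"F{f}-F{s}/layer{layer}")
    return matrix, labels


# ---------------------------------------------------------------------------
# Inter-filament contact series
# ---------------------------------------------------------------------------

def interfilament_series(frames: TrajectoryFrames, model: FibrilModel,
                         cd: ContactDefinition = ContactDefinition(),
                         normalization: str = "per_layer") -> ContactSeries:
    """Atom-pair contact counts between each filament pair, per frame.

    Counts run over *all* layers of both filaments; ``per_layer`` divides
    by the layer count so magnitudes are comparable across stack sizes.
    """
    if model.n_filaments != 3:
        raise TopologyError(
            f"inter-filament series requires 3 filaments, "
            f"found {model.n_filaments}")
    if normalization not in ("raw", "per_layer"):
        raise ArgumentError(f"unknown normalization {normalization!r}")
    fil_idx = {}
    for f in range(1, 4):
        idx = model.atom_indices(chain_id=model.filament_chains(f))
        fil_idx[f] = _filter_scope(model, idx, cd)
    scale = model.n_layers if normalization == "per_layer" else 1
    counts = np.empty((frames.n_frames, len(FILAMENT_PAIRS)))
    for t, frame in enumerate(frames):
        for k, (i, j) in enumerate(FILAMENT_PAIRS):
            counts[t, k] = _count_contacts(frame[fil_idx[i]],
                                           frame[fil_idx[j]],
                                           cd.cutoff) / scale
    return ContactSeries(FILAMENT_PAIRS, counts, counts.sum(axis=1),
                         normalization, frames.times)
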