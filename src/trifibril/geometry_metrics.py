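"""Per-frame structural order parameters of a three-fold fibril.

Implements the trajectory observables used to monitor fibril integrity:

* the mean inter-filament angle φ — for each filament an axis vector is
  drawn between the Phe19 Cα atoms of its two outermost layers, and φ is
  the arc-cosine of the normalized dot product averaged over the three
  filament pairs (≈0° for an untwisted, well-aligned stack);
* the central-pore dimension, read as the mean intra-layer Met35
  side-chain distance between the three chains of a layer;
* backbone RMSD after optimal rigid-body superposition and backbone RMSF
  about the time-average structure (residues 9–40 by default, leaving out
  the flexible N-terminal arm);
* the mass-weighted radius of gyration, whole-assembly or per-layer mean;
* arbitrary named residue-pair distances (e.g. Asp7–Asp7 across layers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import ArgumentError, CongruenceError, GeometryError, SelectionError
from .structure_io import FibrilModel, TrajectoryFrames

__all__ = [
    "FilamentAxis",
    "AngleSeries",
    "PoreSeries",
    "filament_axes",
    "pairwise_axis_angles",
    "mean_axis_angle",
    "mean_interfilament_angle",
    "angle_series",
    "pore_distance",
    "pore_series",
    "superpose",
    "backbone_rmsd",
    "backbone_rmsf",
    "radius_of_gyration",
    "residue_pair_distance",
    "twist_rate_from_angles",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: monoisotopic-ish average masses for mass weighting; unknown elements
#: fall back to carbon (coarse models use C pseudo-atoms)
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "NA": 22.990, "P": 30.974,
}


@dataclass(frozen=True)
class FilamentAxis:
    """Axis vector of one filament: Phe19 Cα (bottom layer) -> Phe19 Cα (top)."""

    filament_index: int
    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float).reshape(3))
        if not np.linalg.norm(self.v) > 0:
            raise GeometryError(
                f"filament {self.filament_index} axis has zero norm")


@dataclass(frozen=True)
class AngleSeries:
    """Mean inter-filament angle per frame, degrees in [0, 180]."""

    phi: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


@dataclass(frozen=True)
class PoreSeries:
    """Per-frame mean Met35–Met35 pore distance, optionally per layer."""

    mean: np.ndarray
    per_layer: np.ndarray  # shape (n_frames, n_layers)
    times: np.ndarray


# ---------------------------------------------------------------------------
# Filament axes and the inter-filament angle
# ---------------------------------------------------------------------------

def _phe19_ca(frame, model, filament, layer):
    chain = model.chain_of(filament, layer)
    idx = model.atom_indices(chain_id=chain, res_id=19, atom_name="CA")
    if len(idx) == 0:
        raise SelectionError(
            f"no Phe19 CA atom in filament {filament}, layer {layer} "
            f"(chain {chain!r})")
    return frame[int(idx[0])]


def filament_axes(frame: np.ndarray, model: FibrilModel) -> list[FilamentAxis]:
    """One axis per filament from the two outermost layers' Phe19 Cα atoms.

    For a periodic (infinite) fibril the outermost layers are the first
    and last layers of the primary cell.
    """
    if model.n_layers < 2:
        raise ArgumentError("filament axes need at least two layers")
    axes = []
    for f in range(1, model.n_filaments + 1):
        bottom = _phe19_ca(frame, model, f, 1)
        top = _phe19_ca(frame, model, f, model.n_layers)
        axes.append(FilamentAxis(f, top - bottom))
    return axes


def pairwise_axis_angles(axes) -> np.ndarray:
    """Angles (degrees) between all unordered axis pairs, dot clamped to [-1, 1]."""
    vs = [a.v if isinstance(a, FilamentAxis) else np.asarray(a, float)
          for a in axes]
    out = []
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            ni, nj = np.linalg.norm(vs[i]), np.linalg.norm(vs[j])
            if ni == 0 or nj == 0:
                raise GeometryError("degenerate zero-norm axis")
            c = np.clip(np.dot(vs[i], vs[j]) / (ni * nj), -1.0, 1.0)
            out.append(np.degrees(np.arccos(c)))
    return np.array(out)


def mean_axis_angle(axes) -> float:
    """Mean pairwise angle over the unordered axis pairs, degrees."""
    return float(pairwise_axis_angles(axes).mean())


def mean_interfilament_angle(frame: np.ndarray, model: FibrilModel) -> float:
    """Mean angle φ between the three filament axes of one frame, degrees."""
    return mean_axis_angle(filament_axes(frame, model))


def angle_series(frames: TrajectoryFrames, model: FibrilModel) -> AngleSeries:
    phi = np.array([mean_interfilament_angle(f, model) for f in frames])
    return AngleSeries(phi, frames.times)


def twist_rate_from_angles(phi_deg, times) -> float:
    """Per-filament tilt rate (deg/frame-time) from a mean-angle series.

    For three filaments tilted by the same angle α about radial axes 120°
    apart, every pairwise angle satisfies cos φ = 1 − 1.5 sin²α, so
    α = asin(√((1 − cos φ)/1.5)) inverts the observable exactly; the rate
    is the least-squares slope of α(t).
    """
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    times = np.asarray(times, dtype=float)
    s2 = np.clip((1.0 - np.cos(phi)) / 1.5, 0.0, 1.0)
    alpha = np.degrees(np.arcsin(np.sqrt(s2)))
    slope = np.polyfit(times, alpha, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Pore dimension
# ---------------------------------------------------------------------------

def pore_distance(frame: np.ndarray, model: FibrilModel, layer: int,
                  met_atom: str = "SD") -> float:
    """Mean Met35–Met35 distance between the three chains of one layer, Å.

    ``met_atom`` selects the side-chain reference atom (sulfur ``SD`` by
    default; ``CE`` or ``sidechain_centroid`` are accepted).
    """
    points = []
    for f in range(1, model.n_filaments + 1):
        chain = model.chain_of(f, layer)
        if met_atom == "sidechain_centroid":
            idx = model.atom_indices(chain_id=chain, res_id=35, heavy_only=True)
            idx = idx[~np.isin(model.atom_name[idx], BACKBONE_NAMES)]
        else:
            idx = model.atom_indices(chain_id=chain, res_id=35,
                                     atom_name=met_atom)
        if len(idx) == 0:
            raise SelectionError(
                f"no Met35 reference atom ({met_atom}) in chain {chain!r}")
        points.append(frame[idx].mean(axis=0))
    points = np.array(points)
    dists = [np.linalg.norm(points[i] - points[j])
             for i in range(len(points)) for j in range(i + 1, len(points))]
    return float(np.mean(dists))


def pore_series(frames: TrajectoryFrames, model: FibrilModel,
                met_atom: str = "SD") -> PoreSeries:
    """Pore dimension per frame: per-layer values and their layer mean."""
    per_layer = np.array(
        [[pore_distance(f, model, layer, met_atom)
          for layer in range(1, model.n_layers + 1)] for f in frames])
    return PoreSeries(per_layer.mean(axis=1), per_layer, frames.times)


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid-body superposition of *mobile* onto *reference*.

    Returns ``(transformed, rmsd)``; rotation from the Kabsch solution as
    implemented by scipy's ``Rotation.align_vectors``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise CongruenceError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    moved = rot.apply(mobile - mc) + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def _backbone_indices(model: FibrilModel, residue_range):
    idx = model.atom_indices(res_range=residue_range, atom_name=BACKBONE_NAMES)
    if len(idx) == 0:
        raise SelectionError(
            f"no backbone atoms in residue range {residue_range}")
    return idx


def backbone_rmsd(frame: np.ndarray, reference: np.ndarray,
                  model: FibrilModel, residue_range=(9, 40),
                  fit: bool = True) -> float:
    """Backbone RMSD between two frames after optimal superposition, Å."""
    idx = _backbone_indices(model, residue_range)
    a, b = frame[idx], reference[idx]
    if fit:
        return superpose(a, b)[1]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def backbone_rmsf(frames: TrajectoryFrames, model: FibrilModel,
                  residue_range=(9, 40), reference: np.ndarray | None = None,
                  fit: bool = True, reduction: str = "atom"):
    """Backbone RMSF about the time-average structure.

    Each frame is first superposed onto *reference* (default: first frame).
    Returns ``(per_residue, mean)`` where ``per_residue`` maps residue
    number to its mean backbone-atom RMSF.  ``reduction`` selects whether
    the scalar mean averages over atoms (``"atom"``) or over the
    per-residue values (``"residue"``); both readings are exposed because
    either may be meant by a "mean RMSF".
    """
    if frames.n_frames < 2:
        raise ArgumentError("RMSF needs at least two frames")
    idx = _backbone_indices(model, residue_range)
    ref = (frames.coords[0] if reference is None else reference)[idx]
    stack = np.empty((frames.n_frames, len(idx), 3))
    for t, frame in enumerate(frames):
        stack[t] = superpose(frame[idx], ref)[0] if fit else frame[idx]
    mean_structure = stack.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stack - mean_structure) ** 2, axis=2),
                               axis=0))
    res_ids = model.res_id[idx]
    per_residue = {int(r): float(per_atom[res_ids == r].mean())
                   for r in np.unique(res_ids)}
    if reduction == "atom":
        mean = float(per_atom.mean())
    elif reduction == "residue":
        mean = float(np.mean(list(per_residue.values())))
    else:
        raise ArgumentError(f"unknown reduction {reduction!r}")
    return per_residue, mean


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def _masses(model: FibrilModel, idx) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(e.upper(), 12.011)
                     for e in model.element[idx]])


def _rg(points: np.ndarray, masses: np.ndarray) -> float:
    com = np.average(points, axis=0, weights=masses)
    sq = np.sum((points - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def radius_of_gyration(frame: np.ndarray, model: FibrilModel,
                       scope: str = "whole") -> float:
    """Mass-weighted radius of gyration, Å.

    ``scope="whole"`` uses every atom; ``"per_layer_mean"`` computes the
    Rg of each layer's chains and averages over layers.
    """
    if scope == "whole":
        idx = np.arange(model.n_atoms)
        if len(idx) == 0:
            raise SelectionError("empty selection")
        return _rg(frame[idx], _masses(model, idx))
    if scope == "per_layer_mean":
        model._require_topology()
        values = []
        for layer in range(1, model.n_layers + 1):
            chains = [model.chain_of(f, layer)
                      for f in range(1, model.n_filaments + 1)]
            idx = model.atom_indices(chain_id=chains)
            if len(idx) == 0:
                raise SelectionError(f"layer {layer} selects no atoms")
            values.append(_rg(frame[idx], _masses(model, idx)))
        return float(np.mean(values))
    raise ArgumentError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Named residue-pair distances
# ---------------------------------------------------------------------------

def residue_pair_distance(frame: np.ndarray, model: FibrilModel,
                          chain_a: str, res_a: int, chain_b: str, res_b: int,
                          mode: str = "min_heavy",
                          atoms: tuple[str, str] | None = None,
                          sidechain_only: bool = False) -> float:
    """Distance between two residues, Å.

    ``mode="min_heavy"`` (default) is the minimum heavy-atom distance;
    ``mode="named_atoms"`` measures between two named atoms given as
    ``atoms=(name_a, name_b)``.  ``sidechain_only`` drops backbone atoms
    from the min-heavy selection.
    """
    def _sel(chain, res, name=None):
        idx = model.atom_indices(chain_id=chain, res_id=res,
                                 atom_name=name, heavy_only=(name is None))
        if name is None and sidechain_only:
            idx = idx[~np.isin(model.atom_name[idx], BACKBONE_NAMES)]
        if len(idx) == 0:
            raise SelectionError(
                f"residue {res} of chain {chain!r} has no matching atoms")
        return idx

    if mode == "min_heavy":
        ia, ib = _sel(chain_a, res_a), _sel(chain_b, res_b)
        return float(cdist(frame[ia], frame[ib]).min())
    if mode == "named_atoms":
        if atoms is None:
            raise ArgumentError("mode='named_atoms' requires atoms=(a, b)")
        ia = _sel(chain_a, res_a, atoms[0])
        ib = _sel(chain_b, res_b, atoms[1])
        return float(np.linalg.norm(frame[int(ia[0])] - frame[int(ib[0])]))
    raise ArgumentError(f"unknown mode {mode!r}")
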