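"""Idealized three-fold fibril structures and rigid-body synthetic trajectories.

Every analysis stage of this package is exercised on structures from this
generator, so molecular-dynamics output (or any download) is never needed
for testing.  The generator emulates the *phenomenology* of an amyloid
fibril with C3 symmetry, not its physics:

* three filaments placed by 120° rotation about the z (fibril) axis,
  layers exactly in register at the cross-beta spacing (4.8 Å default);
* a coarse chain representation — one Cα per residue tracing the
  strand-loop-strand fold, plus named side-chain reference atoms for
  every residue an analysis metric addresses (Phe19 CA for the filament
  axes, Met35 SD lining the central pore, the N-terminal arm residues
  Arg5/Asp7/Ser8 and their turn partners Glu22/Asp23/Val24/Ser26/Asn27);
* an engineered C-terminal interface: each chain carries small combs of
  donor/acceptor pseudo-atoms facing its cyclic neighbor, so adjacent
  filaments share a well-defined, countable set of 4 Å atom-pair
  contacts per layer;
* an N-terminal arm reaching the cyclic neighbor's turn region so that
  exactly the experimentally seen polar pairs Arg5–Glu22, Arg5–Val24,
  Asp7–Ser26 and Ser8–Ser26 are within the 4 Å cutoff by construction.

Trajectories are per-filament rigid-body transforms plus i.i.d. Gaussian
coordinate jitter; four modes mirror the observed end states: ``stable``
(jitter only), ``twist`` (filament tilts growing linearly), ``dissociate``
(all filaments drift apart radially) and ``two_plus_one`` (one filament
detaches while the other two close their interface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ArgumentError
from .fibril_builder import (
    ABETA40_SEQUENCE,
    DisplacementVector,
    replicate_layers,
)
from .structure_io import FibrilModel, TrajectoryFrames, assign_topology

__all__ = [
    "FibrilBlueprint",
    "SyntheticTrajectoryConfig",
    "build_ideal_fibril",
    "simulate_trajectory",
    "fixture_suite",
    "ENGINEERED_ARM_CONTACTS",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: residue pairs (arm residue, turn residue of the cyclic successor chain)
#: placed within the 4 Å contact cutoff by construction
ENGINEERED_ARM_CONTACTS = ((5, 22), (5, 24), (7, 26), (8, 26))

# --- chain template geometry (local polar coordinates per chain) -----------
# Angles in degrees relative to the chain's filament direction; radius in Å;
# z relative to the chain's layer plane.  The fold is idealized: an
# N-terminal strand and a C-terminal strand on radial rays, a turn arc
# connecting them, and the N-terminal arm swung around to the successor
# filament's turn region.

_ARM_RADIUS = 23.5            # residues 1-8 Cα
_NSTRAND_ANGLE = -18.0        # residues 9-20
_TURN_RADIUS = 17.8           # residues 21-30 Cα arc
_TURN_SPAN = 16.0
_CSTRAND_ANGLE = 18.0         # residues 31-40

# C-terminal interface comb: each interface residue (31-40) carries one
# donor atom facing the successor filament and one acceptor facing the
# predecessor, staggered in z across residues.  The resulting atom-pair
# count per interface and layer lands at the tens-of-contacts scale of an
# intact all-atom interface and roughly triples when the gap closes.
_IF_RADIUS = 8.0
_IF_ANGLE = 47.0              # donors at +47°, acceptors at -47°
_IF_Z_STEP = 0.48             # Å of z stagger between consecutive residues

#: xy half-gap between a donor and the matching acceptor of the successor
#: (they sit 20° apart on the interface circle); the two_plus_one mode
#: closes exactly this gap per filament
_PAIR_HALF_GAP = _IF_RADIUS * np.sin(np.radians((120.0 - 2 * _IF_ANGLE) / 2))

# arm/turn side-chain reference atoms: (atom name, element, radius, local
# angle, z offset).  Arm atoms are expressed near the successor's turn
# (local angle ≈ 120° - turn offset).  Up-pointing turn targets sit at
# z +2.6, engaged arm atoms at +2.8; unengaged turn side chains point down
# (z -2.0) so they stay out of the cutoff by construction.
_TURN_SIDECHAINS = {
    22: ("OE1", "O", 19.8, -12.0, 2.6),
    23: ("OD1", "O", 19.2, None, -2.0),    # None: at the residue's Cα angle
    24: ("CG1", "C", 19.8, 0.0, 2.6),
    26: ("OG", "O", 19.8, 14.0, 2.6),
    27: ("ND2", "N", 16.6, None, -2.0),
}
_ARM_SIDECHAINS = {
    5: (("NH1", "N", 21.0, 108.0, 2.8), ("CD", "C", 21.0, 120.0, 2.8)),
    7: (("OD1", "O", 21.0, 132.5, 2.8),),
    8: (("OG", "O", 21.0, 135.5, 2.8),),
}


@dataclass(frozen=True)
class FibrilBlueprint:
    """Parameters of the idealized C3 fibril.

    ``pore_radius`` is the distance of the Met35 SD atoms from the fibril
    axis; by C3 symmetry the intra-layer Met35 triangle side (the pore
    dimension) is exactly ``sqrt(3) * pore_radius`` (≈19.9 Å for the
    default, the ~20 Å pore of a relaxed fibril; 13.28 Å reproduces the
    23 Å of the experimental template).  ``sequence`` must be a
    C-terminal-anchored slice of the Aβ40 sequence (full length or a
    truncation such as Aβ9–40).
    """

    n_layers: int = 6
    layer_spacing: float = 4.8
    pore_radius: float = 11.5
    sequence: str = ABETA40_SEQUENCE

    def __post_init__(self):
        if self.n_layers < 1:
            raise ArgumentError("n_layers must be >= 1")
        if self.layer_spacing <= 0 or self.pore_radius <= 0:
            raise ArgumentError("layer_spacing and pore_radius must be positive")
        if not ABETA40_SEQUENCE.endswith(self.sequence) or not self.sequence:
            raise ArgumentError(
                "sequence must be a C-terminal slice of the Aβ40 sequence")

    @property
    def first_residue(self) -> int:
        return len(ABETA40_SEQUENCE) - len(self.sequence) + 1

    @property
    def designed_pore_distance(self) -> float:
        return float(np.sqrt(3.0) * self.pore_radius)


@dataclass(frozen=True)
class SyntheticTrajectoryConfig:
    """Mode, amplitude and noise of a rigid-body synthetic trajectory.

    ``amplitude`` is mode-specific: tilt rate in degrees/frame (twist),
    outward drift velocity in Å/frame (dissociate), or total detachment
    distance in Å (two_plus_one).  ``None`` selects a mode default.
    """

    mode: str = "stable"
    n_frames: int = 50
    amplitude: float | None = None
    jitter_sigma: float = 0.1
    seed: int = 0

    _DEFAULT_AMPLITUDE = {
        "stable": 0.0, "twist": 0.05, "dissociate": 1.0, "two_plus_one": 30.0,
    }

    def __post_init__(self):
        if self.mode not in self._DEFAULT_AMPLITUDE:
            raise ArgumentError(f"unknown trajectory mode {self.mode!r}")
        if self.n_frames < 2:
            raise ArgumentError("n_frames must be >= 2")
        if self.jitter_sigma < 0:
            raise ArgumentError("jitter_sigma must be >= 0")

    @property
    def effective_amplitude(self) -> float:
        if self.amplitude is None:
            return self._DEFAULT_AMPLITUDE[self.mode]
        return float(self.amplitude)


# ---------------------------------------------------------------------------
# Structure generation
# ---------------------------------------------------------------------------

def _polar(radius: float, angle_deg: float, z: float = 0.0) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def _ca_position(res: int) -> np.ndarray:
    """Cα of residue *res* (1-40) in the chain's local frame."""
    if res <= 8:            # N-terminal arm, swung to the successor's turn
        return _polar(_ARM_RADIUS, 60.0 + (res - 1) * 10.0)
    if res <= 20:           # N-terminal strand, radial ray
        return _polar(5.0 + (res - 9) * 1.0, _NSTRAND_ANGLE)
    if res <= 30:           # turn arc
        return _polar(_TURN_RADIUS, _turn_angle(res))
    # C-terminal strand, radial ray towards the pore
    return _polar(17.0 - (res - 31) * (13.0 / 9.0), _CSTRAND_ANGLE)


def _turn_angle(res: int) -> float:
    return -_TURN_SPAN + (res - 21) * (2 * _TURN_SPAN / 9.0)


def _chain_atoms(bp: FibrilBlueprint):
    """(atom_name, element, res_name, res_id, position) for one chain."""
    atoms = []
    for offset, letter in enumerate(bp.sequence):
        res = bp.first_residue + offset
        res_name = _ONE_TO_THREE[letter]
        atoms.append(("CA", "C", res_name, res, _ca_position(res)))
        if res in _ARM_SIDECHAINS:
            for name, elem, r, ang, z in _ARM_SIDECHAINS[res]:
                atoms.append((name, elem, res_name, res, _polar(r, ang, z)))
        if res in _TURN_SIDECHAINS:
            name, elem, r, ang, z = _TURN_SIDECHAINS[res]
            if ang is None:
                ang = _turn_angle(res)
            atoms.append((name, elem, res_name, res, _polar(r, ang, z)))
        if res == 35:
            atoms.append(("SD", "S", res_name, res,
                          _polar(bp.pore_radius, 0.0)))
        if 31 <= res <= 40:  # interface comb rung
            z = (res - 35.5) * _IF_Z_STEP
            atoms.append(("XD", "C", res_name, res,
                          _polar(_IF_RADIUS, _IF_ANGLE, z)))
            atoms.append(("XA", "C", res_name, res,
                          _polar(_IF_RADIUS, -_IF_ANGLE, z)))
    return atoms


def build_ideal_fibril(bp: FibrilBlueprint = FibrilBlueprint()) -> FibrilModel:
    """Construct the idealized fibril with exact C3 symmetry about z.

    The single template layer is built analytically and stacked with
    :func:`trifibril.fibril_builder.replicate_layers`, so
    ``mean_layer_displacement`` recovers ``(0, 0, layer_spacing)`` exactly
    and the inter-filament angle of the result is identically zero.
    """
    atoms = _chain_atoms(bp)
    cols = {k: [] for k in ("serial", "atom_name", "res_name", "res_id",
                            "chain_id", "coord", "element")}
    serial = 0
    for fil, chain_id in enumerate("ABC"):
        rot = Rotation.from_euler("z", 120.0 * fil, degrees=True)
        for name, elem, res_name, res_id, pos in atoms:
            serial += 1
            cols["serial"].append(serial)
            cols["atom_name"].append(name)
            cols["res_name"].append(res_name)
            cols["res_id"].append(res_id)
            cols["chain_id"].append(chain_id)
            cols["coord"].append(rot.apply(pos))
            cols["element"].append(elem)
    layer = FibrilModel(cols["serial"], cols["atom_name"], cols["res_name"],
                        cols["res_id"], cols["chain_id"],
                        np.array(cols["coord"]), cols["element"])
    layer = assign_topology(layer, n_filaments=3, n_layers=1)
    v = DisplacementVector(np.array([0.0, 0.0, bp.layer_spacing]))
    return replicate_layers(layer, v, bp.n_layers)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _ramp(t: float, start: float, stop: float) -> float:
    """Piecewise-linear 0 -> 1 ramp on [start, stop]."""
    if stop <= start:
        return 1.0 if t >= stop else 0.0
    return float(np.clip((t - start) / (stop - start), 0.0, 1.0))


def simulate_trajectory(model: FibrilModel,
                        cfg: SyntheticTrajectoryConfig) -> TrajectoryFrames:
    """Generate rigid-body frames for *model* under the configured mode.

    Each frame applies a per-filament rigid transform to the base
    coordinates and adds i.i.d. Gaussian jitter (``jitter_sigma``) drawn
    from ``numpy.random.default_rng(seed)``; identical configurations
    reproduce identical frames bit for bit.
    """
    model._require_topology()
    rng = np.random.default_rng(cfg.seed)
    fil_idx = {f: model.atom_indices(chain_id=model.filament_chains(f))
               for f in range(1, model.n_filaments + 1)}
    centroids = {f: model.coord[idx].mean(axis=0)
                 for f, idx in fil_idx.items()}
    # radial (xy) unit vector of each filament, from the fibril axis
    radials = {}
    for f, c in centroids.items():
        r = np.array([c[0], c[1], 0.0])
        n = np.linalg.norm(r)
        radials[f] = r / n if n > 0 else np.array([1.0, 0.0, 0.0])

    amp = cfg.effective_amplitude
    horizon = cfg.n_frames - 1
    frames = np.empty((cfg.n_frames, model.n_atoms, 3))
    for t in range(cfg.n_frames):
        coords = model.coord.copy()
        if cfg.mode == "twist":
            for f, idx in fil_idx.items():
                rot = Rotation.from_rotvec(np.radians(amp * t) * radials[f])
                coords[idx] = rot.apply(coords[idx] - centroids[f]) + centroids[f]
        elif cfg.mode == "dissociate":
            for f, idx in fil_idx.items():
                coords[idx] += amp * t * radials[f]
        elif cfg.mode == "two_plus_one":
            # filament 1 detaches early; 2 and 3 then close their interface
            # by exactly the donor/acceptor half-gap each, so the shared
            # interface is reinforced while both interfaces to filament 1
            # empty out: total contacts dip, then partially recover
            detach = amp * _ramp(t, 0.0, 0.4 * horizon)
            closure = _PAIR_HALF_GAP * _ramp(t, 0.2 * horizon, 0.8 * horizon)
            coords[fil_idx[1]] += detach * radials[1]
            d23 = centroids[3] - centroids[2]
            d23 = np.array([d23[0], d23[1], 0.0])
            d23 /= np.linalg.norm(d23)
            coords[fil_idx[2]] += closure * d23
            coords[fil_idx[3]] -= closure * d23
        if cfg.jitter_sigma > 0:
            coords += rng.normal(0.0, cfg.jitter_sigma, coords.shape)
        frames[t] = coords
    return TrajectoryFrames(frames)


def expected_end_state(mode: str) -> str:
    """Topology label a default-threshold classifier should assign at the end."""
    return {"stable": "TRIPLE", "twist": "TRIPLE",
            "dissociate": "DISSOCIATED", "two_plus_one": "TWO_PLUS_ONE"}[mode]


def fixture_suite(seed: int = 1234, n_layers: int = 6,
                  n_frames: int = 40) -> dict:
    """Deterministic named fixtures used across the test suites.

    Returns ``{name: {"model", "frames", "config", "expected"}}`` with one
    entry per trajectory mode; ``expected`` records the generator ground
    truth (end-state label, designed pore distance, applied tilt rate).
    """
    bp = FibrilBlueprint(n_layers=n_layers)
    model = build_ideal_fibril(bp)
    suite = {}
    for i, mode in enumerate(("stable", "twist", "dissociate", "two_plus_one")):
        cfg = SyntheticTrajectoryConfig(mode=mode, n_frames=n_frames,
                                        seed=seed + i)
        suite[mode] = {
            "model": model,
            "frames": simulate_trajectory(model, cfg),
            "config": cfg,
            "expected": {
                "end_state": expected_end_state(mode),
                "pore_distance": bp.designed_pore_distance,
                "tilt_rate": cfg.effective_amplitude if mode == "twist" else 0.0,
                "layer_spacing": bp.layer_spacing,
            },
        }
    return suite
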