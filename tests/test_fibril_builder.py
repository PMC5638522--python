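"""Layer replication, truncation/capping and composition bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trifibril import (
    ABETA40_SEQUENCE,
    BoxSpec,
    DisplacementVector,
    FibrilModel,
    assign_topology,
    count_chain_atoms,
    mean_layer_displacement,
    net_chain_charge,
    periodic_z_adjustment,
    prune_waters_outside,
    replicate_layers,
    system_composition,
    truncate_n_terminus,
)
from trifibril.errors import ArgumentError, GeometryError, SequenceError
from trifibril.fibril_builder import _RESIDUE_ATOMS

AA = "".join(_RESIDUE_ATOMS)


def _single_layer(n_chains=3):
    cols = {k: [] for k in ("serial", "atom_name", "res_name", "res_id",
                            "chain_id", "coord", "element")}
    s = 0
    for c in range(n_chains):
        for r in (1, 2):
            for name in ("N", "CA"):
                s += 1
                cols["serial"].append(s)
                cols["atom_name"].append(name)
                cols["res_name"].append("GLY")
                cols["res_id"].append(r)
                cols["chain_id"].append("XYZ"[c])
                cols["coord"].append([10.0 * c + s * 0.1, r * 1.5, 0.0])
                cols["element"].append(name[0])
    model = FibrilModel(cols["serial"], cols["atom_name"], cols["res_name"],
                        cols["res_id"], cols["chain_id"],
                        np.array(cols["coord"]), cols["element"])
    return assign_topology(model, n_chains, 1)


def _full_atom_chain():
    """One Aβ1-40 chain with the correct per-residue atom multiplicities.

    Coordinates are placeholders; only N/CA names matter geometrically
    (cap anchoring), the rest are filler atoms so that the chain carries
    exactly the all-atom count of the charged-termini peptide.
    """
    cols = {k: [] for k in ("serial", "atom_name", "res_name", "res_id",
                            "chain_id", "coord", "element")}
    s = 0

    def add(name, elem, res, letter):
        nonlocal s
        s += 1
        cols["serial"].append(s)
        cols["atom_name"].append(name)
        cols["res_name"].append("UNK")
        cols["res_id"].append(res)
        cols["chain_id"].append("A")
        cols["coord"].append([res * 3.8, (s % 7) * 0.9, 0.0])
        cols["element"].append(elem)

    for res, letter in enumerate(ABETA40_SEQUENCE, start=1):
        n_atoms = _RESIDUE_ATOMS[letter]
        add("N", "N", res, letter)
        add("CA", "C", res, letter)
        for k in range(n_atoms - 2):
            add(f"Q{k}", "C", res, letter)
        if res == 1:  # charged N-terminus protons
            add("H2", "H", res, letter)
            add("H3", "H", res, letter)
        if res == 40:  # carboxylate oxygen
            add("OXT", "O", res, letter)
    model = FibrilModel(cols["serial"], cols["atom_name"], cols["res_name"],
                        cols["res_id"], cols["chain_id"],
                        np.array(cols["coord"]), cols["element"])
    return assign_topology(model, 1, 1)


# ---------------------------------------------------------------------------
# Replication and the mean displacement vector
# ---------------------------------------------------------------------------

def test_two_layer_offset_recovered_exactly():
    layer = _single_layer()
    v = DisplacementVector([1.0, 2.0, 3.0])
    model = replicate_layers(layer, v, 2)
    np.testing.assert_array_equal(mean_layer_displacement(model).v, v.v)


def test_replication_identity_for_one_layer():
    layer = _single_layer()
    model = replicate_layers(layer, DisplacementVector([0, 0, 4.8]), 1)
    assert model.n_atoms == layer.n_atoms
    np.testing.assert_array_equal(model.coord, layer.coord)


def test_twelve_layer_span():
    layer = _single_layer()
    model = replicate_layers(layer, DisplacementVector([0, 0, 4.8]), 12)
    z1 = model.coord[model.atom_indices(chain_id=model.chain_of(1, 1))][:, 2]
    z12 = model.coord[model.atom_indices(chain_id=model.chain_of(1, 12))][:, 2]
    assert z12.mean() - z1.mean() == pytest.approx(11 * 4.8)


@pytest.mark.parametrize("n_layers", [2, 3, 6])
def test_replicate_then_measure_round_trip(n_layers):
    layer = _single_layer()
    v = DisplacementVector([0.25, -0.5, 4.8])
    model = replicate_layers(layer, v, n_layers)
    np.testing.assert_allclose(mean_layer_displacement(model).v, v.v,
                               atol=1e-12)


def test_insufficient_layers_error():
    layer = _single_layer()
    model = replicate_layers(layer, DisplacementVector([0, 0, 4.8]), 1)
    with pytest.raises(ArgumentError):
        mean_layer_displacement(model)


def test_replicate_rejects_bad_layer_count():
    with pytest.raises(ArgumentError):
        replicate_layers(_single_layer(), DisplacementVector([0, 0, 4.8]), 0)


# ---------------------------------------------------------------------------
# Truncation and capping
# ---------------------------------------------------------------------------

def test_truncation_bookkeeping_598_to_481():
    chain = _full_atom_chain()
    assert chain.n_atoms == 598 == count_chain_atoms(ABETA40_SEQUENCE)
    capped = truncate_n_terminus(chain, 9)
    # residues 1-8 plus the two terminal protons go, six cap atoms come
    assert capped.n_atoms == 481
    assert capped.res_id.min() == 8  # the ACE cap occupies slot 8
    assert sorted(capped.atom_name[capped.res_name == "ACE"]) == sorted(
        ["CH3", "C", "O", "HH31", "HH32", "HH33"])


def test_truncation_is_idempotent():
    chain = _full_atom_chain()
    once = truncate_n_terminus(chain, 9)
    twice = truncate_n_terminus(once, 9)
    assert twice.n_atoms == once.n_atoms
    np.testing.assert_array_equal(twice.res_id, once.res_id)


def test_cap_sits_next_to_the_new_terminus():
    chain = _full_atom_chain()
    capped = truncate_n_terminus(chain, 9)
    n9 = capped.coord[capped.atom_indices(res_id=9, atom_name="N")[0]]
    cap_c = capped.coord[capped.atom_indices(res_id=8, atom_name="C")[0]]
    assert np.linalg.norm(cap_c - n9) == pytest.approx(1.335, abs=1e-6)


def test_truncate_synthetic_fibril_drops_arm(fibril):
    capped = truncate_n_terminus(fibril, 9)
    assert capped.res_id[capped.res_name != "ACE"].min() == 9
    # one cap per chain
    assert np.sum(capped.atom_name == "CH3") == len(fibril.chain_ids())


# ---------------------------------------------------------------------------
# Sequence bookkeeping
# ---------------------------------------------------------------------------

def test_glycine_free_amino_acid_count():
    assert count_chain_atoms("G") == 10


def test_abeta_chain_counts_and_charges():
    assert count_chain_atoms(ABETA40_SEQUENCE) == 598
    assert count_chain_atoms(ABETA40_SEQUENCE[8:], n_terminus="acetyl") == 481
    assert net_chain_charge(ABETA40_SEQUENCE) == -3
    assert net_chain_charge(ABETA40_SEQUENCE[8:], n_terminus="acetyl") == -2
    assert net_chain_charge("GG") == 0


def test_unknown_residue_letter():
    with pytest.raises(SequenceError):
        count_chain_atoms("GXG")


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet=AA, min_size=1, max_size=30),
       st.text(alphabet=AA, min_size=1, max_size=30))
def test_chain_count_and_charge_are_additive(s1, s2):
    """Concatenation adds residue cores; termini are counted once."""
    termini_atoms = 3  # 2 N-terminal H + 1 C-terminal O
    assert (count_chain_atoms(s1 + s2)
            == count_chain_atoms(s1) + count_chain_atoms(s2) - termini_atoms)
    assert (net_chain_charge(s1 + s2)
            == net_chain_charge(s1) + net_chain_charge(s2))


def test_composition_identity_and_neutralization():
    rep = system_composition(3, 6, ABETA40_SEQUENCE, "charged", 1000)
    assert rep.total_atoms == rep.protein_atoms + rep.n_counterions + 3 * 1000
    assert rep.n_counterions == abs(rep.n_chains * rep.net_charge_per_chain)
    dry = system_composition(3, 6, ABETA40_SEQUENCE, "charged", 0)
    assert dry.total_atoms == dry.protein_atoms + dry.n_counterions


def test_positive_net_charge_unsupported():
    with pytest.raises(ArgumentError):
        system_composition(1, 1, "KKK", "charged", 0)


# ---------------------------------------------------------------------------
# Periodic z adjustment and water pruning
# ---------------------------------------------------------------------------

def _stack(n_layers=12, spacing=4.8):
    return replicate_layers(_single_layer(),
                            DisplacementVector([0, 0, spacing]), n_layers)


def test_z_shrink_arithmetic():
    model = _stack()
    extent = 11 * 4.8
    box = BoxSpec("cuboid", (60.0, 60.0, extent + 10.0))  # d_img = 10
    new_z, shrink = periodic_z_adjustment(model, box, 4.8)
    assert shrink == pytest.approx(5.2)
    assert new_z == pytest.approx(extent + 4.8)
    # image spacing after adjustment equals the template spacing exactly
    assert new_z - extent == pytest.approx(4.8)


def test_z_adjustment_fixed_point_and_idempotence():
    model = _stack()
    extent = 11 * 4.8
    box = BoxSpec("cuboid", (60.0, 60.0, extent + 4.8))
    new_z, shrink = periodic_z_adjustment(model, box, 4.8)
    assert shrink == pytest.approx(0.0)
    assert new_z == pytest.approx(box.z_dimension)
    adjusted = BoxSpec("cuboid", (60.0, 60.0, new_z))
    _, shrink2 = periodic_z_adjustment(model, adjusted, 4.8)
    assert shrink2 == pytest.approx(0.0, abs=1e-12)


def test_z_adjustment_rejects_box_smaller_than_fibril():
    model = _stack(n_layers=2)  # extent 4.8 Å along z
    box = BoxSpec("cuboid", (60.0, 60.0, 4.0))
    with pytest.raises(GeometryError):
        periodic_z_adjustment(model, box, 4.8)


def test_prune_waters_half_open_interval():
    box = BoxSpec("cuboid", (30.0, 30.0, 10.0))
    waters = [[1, 1, 5.0], [1, 1, 10.1], [1, 1, 0.0], [1, 1, 10.0]]
    kept, n_deleted = prune_waters_outside(waters, box)
    assert n_deleted == 2  # z=10.1 outside, z=10.0 on the periodic face
    assert [w[2] for w in kept] == [5.0, 0.0]


def test_prune_waters_uniform_fraction(rng):
    old_z, new_z = 100.0, 80.0
    waters = rng.uniform(0, old_z, size=(5000, 3))
    box = BoxSpec("cuboid", (30.0, 30.0, new_z))
    _, n_deleted = prune_waters_outside(list(waters), box)
    assert n_deleted / 5000 == pytest.approx(1 - new_z / old_z, abs=0.02)
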