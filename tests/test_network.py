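"""Connectome construction, mutation and serialization."""

import itertools
import json

import numpy as np
import pytest

import quadgait as qg
from quadgait.network import (FORE_ONLY_POPULATIONS, GIRDLES,
                              SECTION_POPULATIONS, SIDES, mirror_id,
                              population_id)


def brute_force_counts():
    """Independent enumeration of the connection-table expansion.

    Re-derives the population and edge counts from the row structure
    alone: 13 populations in every section plus 2 descending-only ones in
    each fore section; each within-section row expands once per section
    where its source exists, commissural rows once per section,
    homolateral/diagonal rows once per side.
    """
    n_pops = 4 * 13 + 2 * 2
    within_all = 13      # rows valid in every section
    within_fore = 2      # rows whose source/target exist only in fore
    commissural = 4
    cross_girdle = 3 + 3  # homolateral + diagonal, one per side each
    n_conns = within_all * 4 + within_fore * 2 + commissural * 4 \
        + cross_girdle * 2
    return n_pops, n_conns


class TestIntactNetwork:
    def test_population_and_connection_counts(self, intact_net):
        n_pops, n_conns = brute_force_counts()
        assert len(intact_net.populations) == n_pops == 56
        assert len(intact_net.connections) == n_conns == 84

    def test_section_composition(self, intact_net):
        for girdle, side in itertools.product(GIRDLES, SIDES):
            names = {p.name for p in intact_net.populations
                     if p.girdle == girdle and p.side == side}
            expected = set(SECTION_POPULATIONS)
            if girdle == "fore":
                expected |= set(FORE_ONLY_POPULATIONS)
            assert names == expected

    @pytest.mark.parametrize("src,dst,w", [
        ("hind-left-RG-E", "hind-left-Sh2-Hom", 0.50),
        ("hind-left-Sh2-Hom", "fore-left-RG-F", 0.125),
        ("fore-left-RG-F", "fore-left-V2a", 1.00),
        ("fore-left-V0D-diag", "hind-right-RG-F", -0.075),
        ("hind-right-V0V-diag", "fore-left-RG-F", 0.065),
        ("fore-right-Ini-F", "fore-right-RG-E", -1.00),
        ("hind-left-V0D", "hind-right-RG-F", -0.07),
        ("fore-left-Ini-Hom", "hind-left-RG-F", -0.01),
    ])
    def test_tabulated_weights(self, intact_net, src, dst, w):
        assert intact_net.weight(src, dst) == w

    def test_no_ascending_inhibitory_lpns(self, intact_net):
        """Lumbar-to-cervical pathways contain no inhibitory LPNs: the
        descending-only populations are absent from hind sections."""
        hind = [p for p in intact_net.populations if p.girdle == "hind"]
        assert not any(p.name in FORE_ONLY_POPULATIONS for p in hind)
        # and no hind->fore connection carries a negative weight
        for c in intact_net.connections:
            if c.source.startswith("hind") and c.target.startswith("fore"):
                assert c.weight > 0

    def test_drive_coefficients(self, intact_net):
        for p in intact_net.populations:
            if p.name == "RG-E":
                assert p.drive_E == (0.0, 0.1) and p.drive_I == (0.0, 0.0)
            elif p.name == "RG-F":
                assert p.drive_E == (0.1, 0.0)
            elif p.name in ("V0D", "V0D-diag"):
                assert p.drive_I == (0.75, 0.0)
            elif p.name == "V0V":
                assert p.drive_I == (0.15, 0.0)
            else:
                assert p.drive_E == (0.0, 0.0) and p.drive_I == (0.0, 0.0)

    def test_intrinsic_parameters(self, intact_net):
        for p in intact_net.populations:
            if p.rhythmogenic:
                assert p.name in ("RG-F", "RG-E")
                assert p.gL == 4.5 and p.EL == -62.5
            else:
                assert p.gL == 2.8 and p.EL == -60.0

    def test_mirror_symmetry_automorphism(self, intact_net):
        """Swapping left and right maps the weighted digraph onto itself."""
        edges = {(c.source, c.target, c.weight)
                 for c in intact_net.connections}
        mirrored = {(mirror_id(s), mirror_id(t), w) for s, t, w in edges}
        assert mirrored == edges

    def test_fore_hind_asymmetry(self, intact_net):
        """Swapping girdles does NOT map the connection set onto itself
        (descending inhibitory LPNs have no ascending counterpart)."""
        def swap(pid):
            girdle, rest = pid.split("-", 1)
            other = "hind" if girdle == "fore" else "fore"
            return f"{other}-{rest}"

        edges = {(c.source, c.target, c.weight)
                 for c in intact_net.connections}
        swapped = set()
        for s, t, w in edges:
            swapped.add((swap(s), swap(t), w))
        assert swapped != edges

    def test_source_sign_consistency(self, intact_net):
        """Each population is purely excitatory or purely inhibitory."""
        signs = {}
        for c in intact_net.connections:
            name = c.source.split("-", 2)[2]
            sgn = np.sign(c.weight)
            assert signs.setdefault(name, sgn) == sgn


class TestDeletion:
    def test_identity_on_empty_selector(self, intact_net):
        assert qg.delete_populations(intact_net, []) == intact_net

    def test_unknown_selector_names_it(self, intact_net):
        with pytest.raises(KeyError, match="V0X"):
            qg.delete_populations(intact_net, "all V0X")

    def test_all_v0_selector_silences_every_lr_alternation_pathway(
            self, intact_net):
        net = qg.delete_populations(intact_net, "all V0V and V0D")
        deleted_names = {d.split("-", 2)[2] for d in net.deleted}
        assert deleted_names == {"V0V", "V0V-diag", "V0D", "V0D-diag"}
        # 4 V0V + 4 V0D + 2 V0V-diag... V0V-diag exists in all 4 sections
        assert len(net.deleted) == 4 + 4 + 4 + 2

    def test_girdle_qualified_selector(self, intact_net):
        net = qg.delete_populations(intact_net, "fore V0V-diag")
        assert net.deleted == frozenset(
            {"fore-left-V0V-diag", "fore-right-V0V-diag"})

    def test_descending_lpn_alias(self, intact_net):
        net = qg.delete_populations(intact_net, "cervical-to-lumbar LPNs")
        assert all(d.startswith("fore") for d in net.deleted)
        assert {d.split("-", 2)[2] for d in net.deleted} == \
            {"Ini-Hom", "Sh2-Hom", "V0D-diag", "V0V-diag"}
        assert net.deleted == qg.delete_populations(
            intact_net, "descending LPNs").deleted

    def test_deletion_idempotent_and_commutative(self, intact_net):
        a = qg.delete_populations(intact_net, "all V0V")
        assert qg.delete_populations(a, "all V0V").deleted == a.deleted
        ab = qg.delete_populations(a, "all V0D")
        ba = qg.delete_populations(
            qg.delete_populations(intact_net, "all V0D"), "all V0V")
        assert ab.deleted == ba.deleted

    def test_deleted_population_keeps_state_but_not_output(self, intact_net):
        net = qg.delete_populations(intact_net, "all V0V")
        compiled = net.compile()
        assert compiled.n_pop == 56          # still in the state vector
        i = compiled.index_of("fore-left-V0V")
        assert compiled.out_mask[i] == 0.0
        j = compiled.index_of("fore-left-RG-F")
        assert compiled.out_mask[j] == 1.0


class TestPerturbation:
    def test_zero_sigma_is_identity(self, intact_net):
        net = qg.perturb_weights(intact_net, 0.0, seed=5)
        assert [c.weight for c in net.connections] == \
            [c.weight for c in intact_net.connections]

    def test_negative_sigma_rejected(self, intact_net):
        with pytest.raises(ValueError):
            qg.perturb_weights(intact_net, -0.1)

    def test_multiplier_distribution(self, intact_net):
        """Across many draws the multipliers have mean ~1, sd ~sigma_p."""
        sigma = 0.05
        base = np.array([c.weight for c in intact_net.connections])
        factors = []
        for seed in range(200):
            net = qg.perturb_weights(intact_net, sigma, seed=seed)
            w = np.array([c.weight for c in net.connections])
            factors.append(w / base)
        factors = np.concatenate(factors)
        assert abs(factors.mean() - 1.0) < 0.002
        assert abs(factors.std() - sigma) < 0.002

    def test_reproducible_given_seed(self, intact_net):
        a = qg.perturb_weights(intact_net, 0.1, seed=3)
        b = qg.perturb_weights(intact_net, 0.1, seed=3)
        assert a == b
        c = qg.perturb_weights(intact_net, 0.1, seed=4)
        assert a != c


class TestSerialization:
    def test_roundtrip(self, intact_net, tmp_path):
        path = tmp_path / "net.json"
        intact_net.save(path)
        assert qg.NetworkSpec.load(path) == intact_net

    def test_bundled_canonical_file_matches_builder(self, intact_net):
        from importlib import resources
        doc = json.loads(resources.files("quadgait.data")
                         .joinpath("intact_network.json").read_text())
        assert qg.NetworkSpec.from_dict(doc) == intact_net

    def test_invalid_reference_rejected(self, intact_net):
        doc = intact_net.to_dict()
        doc["connections"][0]["src"] = "fore-left-Nonexistent"
        with pytest.raises(ValueError, match="Nonexistent"):
            qg.NetworkSpec.from_dict(doc)
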