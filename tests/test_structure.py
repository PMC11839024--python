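"""Structure loading, distance evaluation, triage, contacts, variants."""

import numpy as np
import pandas as pd
import pytest

from endonet import synthetic
from endonet.structure import (
    Chain,
    StructureModel,
    ca_distance,
    classify_prediction,
    contact_residues,
    evaluate_crosslinks,
    export_pseudobonds,
    load_structure,
    read_pseudobonds,
    trimer_quality,
    variant_interface_scan,
    write_mmcif,
)

from conftest import brute_force_distances


def _model(coords_by_chain, plddt=None, source="synthetic", offsets=None):
    chains = {}
    chain_map = {}
    for i, (cid, coords) in enumerate(coords_by_chain.items()):
        coords = np.asarray(coords, float)
        pl = None
        if plddt is not None:
            pl = np.asarray(plddt.get(cid, np.full(len(coords), 90.0)), float)
        chains[cid] = Chain(coords=coords, plddt=pl)
        off = (offsets or {}).get(cid, 0)
        chain_map[cid] = (f"ACC{cid}", off)
    return StructureModel("toy", source, chains, chain_map)


def _links(rows):
    return pd.DataFrame(
        rows, columns=["accession_a", "pos_a", "accession_b", "pos_b"]
    ).assign(chemistry="DSSO")


class TestIO:
    def test_mmcif_roundtrip_bit_exact(self, shifted_bundle, tmp_path):
        p = write_mmcif(shifted_bundle, tmp_path / "m.cif")
        loaded = load_structure(p, shifted_bundle.chain_map,
                                source="synthetic")
        for cid in shifted_bundle.chains:
            np.testing.assert_array_equal(
                loaded.chains[cid].coords, shifted_bundle.chains[cid].coords
            )
            np.testing.assert_array_equal(
                loaded.chains[cid].plddt, shifted_bundle.chains[cid].plddt
            )

    def test_offset_convention(self):
        m = _model({"A": [[0, 0, 0], [1, 0, 0]]}, offsets={"A": 10})
        # structure residue 1 = full-length position 11
        assert m.resolve("ACCA", 11) == ("A", 0)
        assert m.resolve("ACCA", 10) is None

    def test_missing_chain_named_in_error(self, shifted_bundle, tmp_path):
        p = write_mmcif(shifted_bundle, tmp_path / "m.cif")
        bad_map = dict(shifted_bundle.chain_map)
        bad_map["Z"] = ("ACCZ", 0)
        with pytest.raises(ValueError, match="Z"):
            load_structure(p, bad_map)


class TestCaDistance:
    def test_pythagorean(self):
        m = _model({"A": [[0, 0, 0], [3, 4, 0]]})
        assert ca_distance(m, ("ACCA", 1), ("ACCA", 2)) == 5.0

    def test_same_residue_zero(self):
        m = _model({"A": [[1, 2, 3]]})
        assert ca_distance(m, ("ACCA", 1), ("ACCA", 1)) == 0.0

    def test_matches_longhand_oracle(self, shifted_bundle):
        dists = brute_force_distances(shifted_bundle)
        rng = np.random.default_rng(0)
        keys = list(dists)
        for i in rng.choice(len(keys), size=20, replace=False):
            a_acc, a_pos, b_acc, b_pos = keys[i]
            d = ca_distance(shifted_bundle, (a_acc, a_pos), (b_acc, b_pos))
            assert d == pytest.approx(dists[keys[i]], abs=1e-9)

    def test_unmapped_raises(self):
        m = _model({"A": [[0, 0, 0]]})
        with pytest.raises(KeyError):
            ca_distance(m, ("ACCA", 1), ("ACCA", 99))


class TestEvaluate:
    def test_planted_true_links_all_within(self, shifted_bundle):
        links = synthetic.gen_crosslinks(shifted_bundle, n_true=25,
                                         n_decoy=0, seed=2)
        _, summary = evaluate_crosslinks(shifted_bundle, links,
                                         threshold=35.0)
        assert summary["fraction_within"] == 1.0

    def test_boundary_distance_semantics(self):
        # exactly at the threshold counts as within (<=); just over exceeds
        m = _model({"A": [[0, 0, 0]], "B": [[35.0, 0, 0], [36.0, 0, 0]]})
        evals, _ = evaluate_crosslinks(
            m, _links([("ACCA", 1, "ACCB", 1), ("ACCA", 1, "ACCB", 2)]),
            threshold=35.0,
        )
        assert list(evals["status"]) == ["within", "exceeded"]

    def test_plddt_gate(self):
        # pLDDT 65 -> unstructured regardless of distance; exactly 70 is
        # also excluded (strict > 70 required)
        m = _model(
            {"A": [[0, 0, 0], [1, 0, 0], [2, 0, 0]]},
            plddt={"A": [65.0, 70.0, 90.0]},
        )
        evals, _ = evaluate_crosslinks(
            m,
            _links([("ACCA", 1, "ACCA", 3), ("ACCA", 2, "ACCA", 3)]),
            threshold=35.0,
        )
        assert list(evals["status"]) == ["unstructured", "unstructured"]

    def test_experimental_model_skips_gate(self):
        m = _model({"A": [[0, 0, 0], [1, 0, 0]]}, source="PDB")
        evals, _ = evaluate_crosslinks(
            m, _links([("ACCA", 1, "ACCA", 2)]), threshold=35.0
        )
        assert evals["status"].iloc[0] == "within"

    def test_status_partition_exhaustive(self, shifted_bundle):
        links = synthetic.gen_crosslinks(shifted_bundle, n_true=30,
                                         n_decoy=30, seed=5)
        links.loc[0, "pos_a"] = 9999  # force an unmapped link
        evals, summary = evaluate_crosslinks(shifted_bundle, links)
        assert set(evals["status"]) <= {"within", "exceeded", "unstructured",
                                        "unmapped"}
        assert (summary["n_within"] + summary["n_exceeded"]
                + summary["n_unstructured"] + summary["n_unmapped"]
                == len(links))

    def test_fraction_monotone_in_threshold(self, shifted_bundle):
        links = synthetic.gen_crosslinks(shifted_bundle, n_true=40,
                                         n_decoy=40, seed=6)
        fracs = [
            evaluate_crosslinks(shifted_bundle, links, threshold=t)[1][
                "fraction_within"]
            for t in (10.0, 20.0, 35.0, 60.0, 200.0)
        ]
        assert fracs == sorted(fracs)

    def test_link_assisted_uses_30(self):
        m = _model({"A": [[0, 0, 0]], "B": [[32.0, 0, 0]]},
                   plddt={"A": [90.0], "B": [90.0]},
                   source="link-assisted-prediction")
        evals, _ = evaluate_crosslinks(m, _links([("ACCA", 1, "ACCB", 1)]))
        assert evals["threshold_used"].iloc[0] == 30.0
        assert evals["status"].iloc[0] == "exceeded"

    def test_empty_links(self, shifted_bundle):
        evals, summary = evaluate_crosslinks(
            shifted_bundle, _links([]), threshold=35.0
        )
        assert len(evals) == 0
        assert summary["fraction_within"] is None


class TestClassify:
    def _evals(self, statuses, intra=False):
        return pd.DataFrame(
            {"status": statuses, "is_intra": [intra] * len(statuses)}
        )

    def test_supported(self):
        assert classify_prediction(0.8, self._evals(["within", "within"])) \
            == "supported"

    def test_unstructured_only(self):
        ev = self._evals(["unstructured", "unmapped"])
        assert classify_prediction(0.8, ev) == "unstructured-only"

    def test_low_confidence_any_links(self):
        assert classify_prediction(0.2, self._evals(["within"])) \
            == "low-confidence"

    def test_boundary_spoc_exactly_033(self):
        assert classify_prediction(0.33, self._evals(["within"])) \
            == "low-confidence"

    def test_violated_majority(self):
        ev = self._evals(["within", "exceeded", "exceeded"])
        assert classify_prediction(0.8, ev) == "violated"

    def test_exact_half_is_violated(self):
        ev = self._evals(["within", "exceeded"])
        assert classify_prediction(0.8, ev) == "violated"  # needs > 50%

    def test_order_invariance(self):
        statuses = ["within", "exceeded", "within", "unstructured"]
        cats = {
            classify_prediction(0.8, self._evals(list(perm)))
            for perm in __import__("itertools").permutations(statuses)
        }
        assert len(cats) == 1

    def test_iptm_fallback_and_unscored(self):
        ev = self._evals(["within"])
        assert classify_prediction(None, ev, iptm=0.8) == "supported"
        assert classify_prediction(None, ev) == "unscored"


class TestTrimer:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((0.9, 0.6, 0.1), True),
            ((0.9, 0.5, 0.5), False),  # strict > 0.5
            ((0.51, 0.51, 0.51), True),
            ((0.9, None, 0.6), True),  # missing counts as 0
            ((0.9, None, None), False),
        ],
    )
    def test_acceptance_rule(self, scores, expected):
        assert trimer_quality(scores) is expected

    def test_requires_three_interfaces(self):
        with pytest.raises(ValueError):
            trimer_quality([0.9, 0.9])


class TestContacts:
    def test_parallel_helices_six_angstrom(self):
        m = synthetic.gen_structure([20, 20], chain_spacing=6.0, seed=0)
        contacts = contact_residues(m, "A", "B", contact_cutoff=8.0)
        # facing residues contact; direct distance scan as oracle
        dists = brute_force_distances(m)
        expected_a = {
            pa for (aa, pa, ab, pb), d in dists.items()
            if aa == "SYN000" and ab == "SYN001" and d <= 8.0
        }
        assert contacts["SYN000"] == expected_a
        assert len(expected_a) > 0

    def test_distant_chains_empty(self):
        m = synthetic.gen_structure([10, 10], chain_spacing=50.0, seed=0)
        contacts = contact_residues(m, "A", "B")
        assert contacts["SYN000"] == set() and contacts["SYN001"] == set()

    def test_cutoff_monotonicity(self, shifted_bundle):
        c8 = contact_residues(shifted_bundle, "A", "B", contact_cutoff=8.0)
        c10 = contact_residues(shifted_bundle, "A", "B", contact_cutoff=10.0)
        for acc in c8:
            assert c8[acc] <= c10[acc]


class TestVariantScan:
    def _variants(self, rows):
        return pd.DataFrame(
            rows, columns=["accession", "position"]
        ).assign(ref="A", alt="V", annotation="x")

    def test_hit_at_contact(self):
        out = variant_interface_scan(self._variants([("P", 78)]),
                                     {"P": [78]})
        assert out["near_interface"].iloc[0]
        assert out["gap"].iloc[0] == 0

    def test_boundary_window(self):
        out = variant_interface_scan(
            self._variants([("P", 80), ("P", 81)]), {"P": [78]}, window=2
        )
        assert list(out["near_interface"]) == [True, False]

    def test_planted_recovery(self, shifted_bundle):
        contacts = contact_residues(shifted_bundle, "A", "B")
        v = synthetic.gen_variants(shifted_bundle, contacts, n_near=3,
                                   n_far=3, seed=4)
        out = variant_interface_scan(v, contacts, window=2)
        assert (out["near_interface"] == out["true_near"]).all()

    def test_no_contacts_no_hits(self):
        out = variant_interface_scan(self._variants([("P", 10)]), {})
        assert not out["near_interface"].any()


class TestPseudobonds:
    def test_export_and_roundtrip(self, shifted_bundle, tmp_path):
        links = synthetic.gen_crosslinks(shifted_bundle, n_true=10,
                                         n_decoy=5, seed=8)
        evals, _ = evaluate_crosslinks(shifted_bundle, links)
        path, skipped = export_pseudobonds(shifted_bundle, evals,
                                           tmp_path / "pb.pb")
        bonds = read_pseudobonds(path)
        n_mapped = int((evals["status"] != "unmapped").sum())
        assert len(bonds) == n_mapped and skipped == 0
        assert all("@CA" in b for b in bonds)

    def test_empty_evaluations_header_only(self, shifted_bundle, tmp_path):
        evals = pd.DataFrame(
            columns=["accession_a", "pos_a", "accession_b", "pos_b",
                     "status"]
        )
        path, skipped = export_pseudobonds(shifted_bundle, evals,
                                           tmp_path / "pb.pb")
        assert read_pseudobonds(path) == []
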