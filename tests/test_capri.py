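"""CAPRI docking-model metrics and quality classification."""

import itertools

import numpy as np
import pytest

from abensemble.capri import (
    QUALITY_ORDER,
    classify_quality,
    evaluate_pose,
    fnat,
    interface_rmsd,
    ligand_rmsd,
    native_contacts,
    success_rate,
)
from abensemble.errors import UndefinedMetricError, ValidationError
from abensemble.fixtures import make_toy_complex
from oracles import brute_force_contacts, capri_class_by_table, random_rigid_transform

FNAT_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 3)
LRMSD_GRID = np.arange(0.5, 12.001, 0.5)
IRMSD_GRID = np.arange(0.5, 5.001, 0.5)


@pytest.fixture(scope="module")
def complex_pair():
    return make_toy_complex(seed=9, interface_size=6)


class TestNativeContacts:
    def test_matches_brute_force_enumeration(self, complex_pair):
        contacts = native_contacts(complex_pair.reference, ["A"], ["B"], cutoff=5.0)
        assert contacts == brute_force_contacts(complex_pair.reference, ["A"], ["B"], 5.0)
        assert contacts == complex_pair.expected_contacts

    def test_distant_chains_have_no_contacts(self, complex_pair):
        far = make_toy_complex(seed=9, interface_size=6, perturbation=((0, 0, 0), (0, 0, 100.0)))
        assert native_contacts(far.model, ["A"], ["B"], cutoff=5.0) == frozenset()

    def test_pairs_cross_the_partition(self, complex_pair):
        for rkey, lkey in native_contacts(complex_pair.reference, ["A"], ["B"]):
            assert rkey[0] == "A" and lkey[0] == "B"

    def test_unknown_chain_is_key_error(self, complex_pair):
        with pytest.raises(KeyError):
            native_contacts(complex_pair.reference, ["A"], ["Z"])

    def test_overlapping_groups_rejected(self, complex_pair):
        with pytest.raises(ValidationError):
            native_contacts(complex_pair.reference, ["A"], ["A"])


class TestFnat:
    def test_self_is_one(self, complex_pair):
        assert fnat(complex_pair.reference, complex_pair.reference, ["A"], ["B"]) == 1.0

    def test_displaced_ligand_is_zero(self):
        far = make_toy_complex(seed=3, interface_size=5, perturbation=((0, 0, 0), (0, 0, 50.0)))
        assert fnat(far.model, far.reference, ["A"], ["B"]) == 0.0

    def test_partial_contact_recovery_matches_brute_force(self):
        tc = make_toy_complex(seed=4, interface_size=8, perturbation=((0, 0, 0.12), (2.0, 0, 0.2)))
        expected = len(
            brute_force_contacts(tc.model, ["A"], ["B"], 5.0) & tc.expected_contacts
        ) / len(tc.expected_contacts)
        assert fnat(tc.model, tc.reference, ["A"], ["B"]) == pytest.approx(expected)
        assert 0.0 < expected < 1.0  # the perturbation must be informative

    def test_no_reference_contacts_is_undefined(self):
        far = make_toy_complex(seed=3, interface_size=5, perturbation=((0, 0, 0), (0, 0, 50.0)))
        with pytest.raises(UndefinedMetricError):
            fnat(far.reference, far.model, ["A"], ["B"])


class TestLigandRmsd:
    def test_self_is_zero(self, complex_pair):
        value = ligand_rmsd(complex_pair.reference, complex_pair.reference, ["A"], ["B"])
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation_measured_exactly(self):
        tc = make_toy_complex(seed=5, interface_size=6, perturbation=((0, 0, 0), (0, 0, 3.0)))
        assert ligand_rmsd(tc.model, tc.reference, ["A"], ["B"]) == pytest.approx(3.0, abs=1e-6)

    def test_seeded_pose_matches_two_step_oracle(self):
        from abensemble.geometry import backbone_coords
        from oracles import plain_rmsd, svd_superpose

        tc = make_toy_complex(seed=6, interface_size=6, perturbation=((0, 0.1, 0.2), (1.0, -0.5, 0.8)))

        def bb(st, cid):
            keys = [(r.seq_id, r.insertion_code) for r in tc.reference.chain(cid).residues]
            return backbone_coords(st, cid, keys)

        R, t = svd_superpose(bb(tc.model, "A"), bb(tc.reference, "A"))
        expected = plain_rmsd(bb(tc.model, "B") @ R.T + t, bb(tc.reference, "B"))
        assert ligand_rmsd(tc.model, tc.reference, ["A"], ["B"]) == pytest.approx(expected, abs=1e-9)


class TestInterfaceRmsd:
    def test_self_is_zero(self, complex_pair):
        value = interface_rmsd(complex_pair.reference, complex_pair.reference, ["A"], ["B"])
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_transform_absorbed(self, complex_pair, rng):
        R, t = random_rigid_transform(rng)
        moved = complex_pair.reference.transform(R, t)
        assert interface_rmsd(moved, complex_pair.reference, ["A"], ["B"]) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_empty_interface_is_undefined(self):
        far = make_toy_complex(seed=3, interface_size=5, perturbation=((0, 0, 0), (0, 0, 50.0)))
        with pytest.raises(UndefinedMetricError):
            interface_rmsd(far.reference, far.model, ["A"], ["B"], interface_cutoff=1.0)


class TestMetricInvariances:
    def test_all_metrics_invariant_under_rigid_transforms(self, complex_pair, rng):
        tc = make_toy_complex(seed=10, interface_size=6, perturbation=((0, 0, 0.1), (0.5, 0.2, 1.0)))
        base = (
            fnat(tc.model, tc.reference, ["A"], ["B"]),
            ligand_rmsd(tc.model, tc.reference, ["A"], ["B"]),
            interface_rmsd(tc.model, tc.reference, ["A"], ["B"]),
        )
        for _ in range(5):
            Rm, tm = random_rigid_transform(rng)
            Rr, tr = random_rigid_transform(rng)
            model = tc.model.transform(Rm, tm)
            reference = tc.reference.transform(Rr, tr)
            moved = (
                fnat(model, reference, ["A"], ["B"]),
                ligand_rmsd(model, reference, ["A"], ["B"]),
                interface_rmsd(model, reference, ["A"], ["B"]),
            )
            assert moved == pytest.approx(base, abs=1e-6)


class TestClassifyQuality:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ((0.6, 0.9, 2.5), "high"),
            ((0.35, 4.0, 3.0), "medium"),
            ((0.05, 0.5, 0.5), "incorrect"),  # fnat gate fails every class
            ((0.2, 8.0, 3.5), "acceptable"),
            ((0.5, 1.0, 1.0), "high"),  # thresholds are inclusive
        ],
    )
    def test_reference_cases(self, scores, expected):
        assert classify_quality(*scores) == expected

    def test_agrees_with_decision_table_on_full_lattice(self):
        for f, l, i in itertools.product(FNAT_GRID, LRMSD_GRID, IRMSD_GRID):
            assert classify_quality(f, l, i) == capri_class_by_table(f, l, i)

    def test_monotone_in_each_score(self):
        """Improving any single score never lowers the class."""
        for f, l, i in itertools.product(FNAT_GRID[::2], LRMSD_GRID[::2], IRMSD_GRID):
            rank = QUALITY_ORDER[classify_quality(f, l, i)]
            if f < 1.0:
                assert QUALITY_ORDER[classify_quality(min(f + 0.05, 1.0), l, i)] >= rank
            assert QUALITY_ORDER[classify_quality(f, max(l - 0.5, 0.0), i)] >= rank
            assert QUALITY_ORDER[classify_quality(f, l, max(i - 0.5, 0.0))] >= rank

    def test_strict_printed_incorrect_mode_differs_where_rules_conflict(self):
        # lrmsd > 10 and 2 < irmsd <= 4 with decent fnat: acceptable by the
        # cascade, incorrect by the printed clause
        assert classify_quality(0.2, 11.0, 3.0) == "acceptable"
        assert classify_quality(0.2, 11.0, 3.0, strict_printed_incorrect=True) == "incorrect"

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValidationError):
            classify_quality(float("nan"), 1.0, 1.0)


class TestSuccessRate:
    def test_six_of_nine_at_rank_one(self):
        runs = {f"t{i}": ["acceptable"] for i in range(6)}
        runs.update({f"u{i}": ["incorrect"] for i in range(3)})
        assert success_rate(runs, top_n=1) == pytest.approx(6 / 9)

    def test_min_quality_incorrect_is_always_one(self):
        runs = [["incorrect"], ["incorrect", "incorrect"]]
        assert success_rate(runs, top_n=1, min_quality="incorrect") == 1.0

    def test_top_n_beyond_run_length_uses_full_run(self):
        runs = [["incorrect", "medium"]]
        assert success_rate(runs, top_n=10, min_quality="medium") == 1.0

    def test_monotone_in_top_n_and_quality(self):
        rng = np.random.default_rng(8)
        classes = list(QUALITY_ORDER)
        runs = [list(rng.choice(classes, size=10)) for _ in range(20)]
        rates_n = [success_rate(runs, top_n=n, min_quality="medium") for n in range(1, 11)]
        assert all(a <= b for a, b in zip(rates_n, rates_n[1:]))
        rates_q = [success_rate(runs, top_n=3, min_quality=q)
                   for q in ["incorrect", "acceptable", "medium", "high"]]
        assert all(a >= b for a, b in zip(rates_q, rates_q[1:]))

    def test_empty_runs_rejected(self):
        with pytest.raises(ValidationError):
            success_rate([], top_n=1)


def test_evaluate_pose_consistent_with_components(complex_pair):
    tc = make_toy_complex(seed=12, interface_size=6, perturbation=((0, 0, 0.05), (0.3, 0, 0.5)))
    scores = evaluate_pose(tc.model, tc.reference, ["A"], ["B"])
    assert scores.fnat == pytest.approx(fnat(tc.model, tc.reference, ["A"], ["B"]))
    assert scores.lrmsd == pytest.approx(ligand_rmsd(tc.model, tc.reference, ["A"], ["B"]))
    assert scores.quality == classify_quality(scores.fnat, scores.lrmsd, scores.irmsd)


def test_unperturbed_pose_scores_perfect(complex_pair):
    scores = evaluate_pose(complex_pair.model, complex_pair.reference, ["A"], ["B"])
    assert scores.fnat == 1.0
    assert scores.lrmsd == pytest.approx(0.0, abs=1e-9)
    assert scores.quality == "high"
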