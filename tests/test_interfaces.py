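"""Interface detection, pDockQ, binding-mode clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from varmech import (
    ComplexModel,
    bin_pdockq,
    cluster_partner_interfaces,
    disruption_enrichment,
    generate_complex,
    generate_hub,
    interface_fraction,
    interface_residues,
    pdockq,
    pdockq_from_interface,
    residue_min_distance,
    select_best_model,
    single_point_chain,
    top_cluster_fractions,
)
from varmech.errors import EmptyInputError, InsufficientDataError, ValidationError
from varmech.interfaces import PDOCKQ_B, PDOCKQ_L, PDOCKQ_X0


def _random_model(rng, max_res=30, spread=25.0):
    na, nb = rng.integers(3, max_res, size=2)
    ca = rng.uniform(-spread, spread, size=(na, 3))
    cb = rng.uniform(-spread, spread, size=(nb, 3))
    a = single_point_chain("A", ca, rng.uniform(40, 98, size=na))
    b = single_point_chain("B", cb, rng.uniform(40, 98, size=nb))
    return ComplexModel(pair_id=("X", "Y"), chain_a=a, chain_b=b), ca, cb


class TestInterfaceResidues:
    def test_planted_contacts_recovered_exactly(self):
        model, pairs = generate_complex(40, 30, n_contact_pairs=6, seed=3)
        imap = interface_residues(model, 5.0)
        assert imap.residues_a == {a for a, _ in pairs}
        assert imap.residues_b == {b for _, b in pairs}

    def test_distant_chains_have_empty_interface(self):
        model, _ = generate_complex(10, 10, n_contact_pairs=0, seed=0)
        imap = interface_residues(model, 5.0)
        assert imap.residues_a == frozenset() and imap.residues_b == frozenset()

    def test_monotone_in_cutoff(self, rng):
        model, _, _ = _random_model(rng)
        sets = [interface_residues(model, c).residues_a for c in (5.0, 8.0, 10.0)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_symmetric_in_chain_order(self, rng):
        model, _, _ = _random_model(rng)
        swapped = ComplexModel(pair_id=("Y", "X"), chain_a=model.chain_b,
                               chain_b=model.chain_a)
        imap, imap_s = interface_residues(model, 6.0), interface_residues(swapped, 6.0)
        assert imap.residues_a == imap_s.residues_b
        assert imap.residues_b == imap_s.residues_a

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            model, ca, cb = _random_model(rng)
            for cutoff in (4.5, 5.0, 8.0):
                imap = interface_residues(model, cutoff)
                d = cdist(ca, cb)
                exp_a = {i + 1 for i in range(len(ca)) if (d[i] < cutoff).any()}
                exp_b = {j + 1 for j in range(len(cb)) if (d[:, j] < cutoff).any()}
                assert imap.residues_a == exp_a
                assert imap.residues_b == exp_b

    def test_invalid_cutoff_rejected(self, rng):
        model, _, _ = _random_model(rng)
        with pytest.raises(ValidationError):
            interface_residues(model, 0.0)


class TestPdockq:
    def test_zero_contacts_gives_floor(self):
        model, _ = generate_complex(10, 8, n_contact_pairs=0, seed=0)
        assert pdockq(model) == pytest.approx(PDOCKQ_B) == pytest.approx(0.018)

    def test_sigmoid_midpoint(self):
        # choose mean pLDDT so that x = mean_plddt * ln(contacts) hits x0
        for n in (5, 20, 100):
            score = pdockq_from_interface(PDOCKQ_X0 / np.log(n), n)
            assert score == pytest.approx(PDOCKQ_L / 2 + PDOCKQ_B) == pytest.approx(0.380)

    def test_strictly_increasing_in_contacts(self):
        scores = [pdockq_from_interface(90.0, n) for n in range(1, 40)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_increasing_with_planted_contact_count(self):
        scores = []
        for k in (2, 6, 12):
            model, _ = generate_complex(60, 50, n_contact_pairs=k,
                                        interface_plddt=90.0, seed=5)
            scores.append(pdockq(model))
        assert scores[0] < scores[1] < scores[2]

    def test_invariant_to_chain_order(self, rng):
        model, _, _ = _random_model(rng)
        swapped = ComplexModel(pair_id=("Y", "X"), chain_a=model.chain_b,
                               chain_b=model.chain_a)
        assert pdockq(model) == pytest.approx(pdockq(swapped), abs=1e-12)

    def test_bounded(self, rng):
        for _ in range(10):
            model, _, _ = _random_model(rng, spread=12.0)
            assert PDOCKQ_B <= pdockq(model) <= PDOCKQ_L + PDOCKQ_B


class TestBinPdockq:
    @pytest.mark.parametrize("score,expected", [
        (0.1, "poor"), (0.23, "weak"), (0.4, "weak"), (0.5, "weak"),
        (0.62, "confident"),
    ])
    def test_bins(self, score, expected):
        assert bin_pdockq(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_pdockq(1.2)


class TestSelectBestModel:
    def test_single_model_returned(self):
        model, _ = generate_complex(10, 10, n_contact_pairs=2, seed=0)
        assert select_best_model([model]) is model

    def test_max_pdockq_wins(self):
        models = []
        for score in (0.3, 0.7, 0.5):
            m, _ = generate_complex(10, 10, n_contact_pairs=1, seed=0)
            m.pdockq = score
            models.append(m)
        best = select_best_model(models)
        assert best.pdockq == 0.7
        assert best.confidence_bin == "confident"

    def test_matches_argmax_on_random_lists(self, rng):
        for _ in range(20):
            scores = rng.random(int(rng.integers(1, 8)))
            models = []
            for s in scores:
                m, _ = generate_complex(6, 6, n_contact_pairs=1, seed=0)
                m.pdockq = float(s)
                models.append(m)
            assert select_best_model(models).pdockq == pytest.approx(scores.max())

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyInputError):
            select_best_model([])


class TestResidueMinDistance:
    def test_planted_contact_below_five(self):
        model, pairs = generate_complex(30, 25, n_contact_pairs=4, seed=9)
        a, b = pairs[0]
        assert residue_min_distance(model, "A", a) < 5.0
        assert residue_min_distance(model, "B", b) < 5.0
        non_contact = next(i for i in range(1, 31) if i not in {x for x, _ in pairs})
        assert residue_min_distance(model, "A", non_contact) > 8.0

    def test_matches_brute_force(self, rng):
        model, ca, cb = _random_model(rng)
        d = cdist(ca, cb)
        for i in range(len(ca)):
            assert residue_min_distance(model, "A", i + 1) == pytest.approx(
                d[i].min(), abs=1e-12)

    def test_missing_residue_rejected(self, rng):
        model, _, _ = _random_model(rng)
        with pytest.raises(KeyError):
            residue_min_distance(model, "A", 9999)


class TestDisruptionEnrichment:
    def _simulate(self, seed, on_interface=True, low_plddt_iface=False):
        rng = np.random.default_rng(seed)
        iface_plddt = 50.0 if low_plddt_iface else 90.0
        model, pairs = generate_complex(60, 50, n_contact_pairs=8,
                                        interface_plddt=iface_plddt, seed=seed)
        iface_a = [a for a, _ in pairs]
        rows = []
        for _ in range(40):
            disrupting = rng.random() < 0.4
            if disrupting and on_interface:
                pos = int(rng.choice(iface_a))
            else:
                pos = int(rng.integers(1, 61))
            rows.append({"pair": ("X", "Y"), "chain_id": "A", "position": pos,
                         "disrupting": disrupting})
        return pd.DataFrame(rows), {("X", "Y"): model}

    def test_planted_interface_mutations_enriched(self):
        wins = 0
        for seed in range(20):
            muts, models = self._simulate(seed)
            res = disruption_enrichment(muts, models, cutoffs=[5.0])
            odds = res.loc[0, "odds_ratio"]
            wins += int(odds > 1.0 or np.isinf(odds))
        assert wins / 20 >= 0.95

    def test_shuffled_labels_are_null(self, rng):
        odds_all = []
        for seed in range(30):
            muts, models = self._simulate(seed, on_interface=False)
            res = disruption_enrichment(muts, models, cutoffs=[5.0])
            o = res.loc[0, "odds_ratio"]
            if np.isfinite(o) and o > 0:
                odds_all.append(np.log(o))
        assert abs(np.median(odds_all)) < 1.0

    def test_low_confidence_filter_raises_enrichment(self):
        # disrupting mutations sit on high-pLDDT interface residues; adding
        # low-confidence interface decoys dilutes the unfiltered test only
        better = 0
        n = 20
        for seed in range(n):
            rng = np.random.default_rng(seed)
            model, pairs = generate_complex(80, 60, n_contact_pairs=12,
                                            interface_plddt=90.0, seed=seed)
            # depress pLDDT on half the interface residues of chain A
            iface_a = sorted(a for a, _ in pairs)
            low = set(iface_a[::2])
            for r in model.chain_a.residues:
                if r.index in low:
                    object.__setattr__(r, "plddt", 55.0)
            high = [a for a in iface_a if a not in low]
            rows = []
            for _ in range(60):
                disrupting = rng.random() < 0.4
                pos = int(rng.choice(high)) if disrupting else int(rng.integers(1, 81))
                rows.append({"pair": ("X", "Y"), "chain_id": "A",
                             "position": pos, "disrupting": disrupting})
            muts = pd.DataFrame(rows)
            unf = disruption_enrichment(muts, {("X", "Y"): model}, [5.0]).loc[0, "odds_ratio"]
            fil = disruption_enrichment(muts, {("X", "Y"): model}, [5.0],
                                        plddt_filter=70.0).loc[0, "odds_ratio"]
            if np.isinf(fil) or fil >= unf:
                better += 1
        assert better / n >= 0.9


class TestClustering:
    def _footprints_from_models(self, hub):
        return {m.pair_id[1]: interface_residues(m, 5.0).residues_a
                for m in hub.partner_models}

    def test_single_mode_gives_one_cluster(self):
        hub = generate_hub(n_partners=8, n_modes=1, mode_overlap=0.1, seed=4)
        hc = cluster_partner_interfaces("HUB", self._footprints_from_models(hub))
        assert hc.n_clusters == 1

    def test_three_planted_modes_recovered(self):
        hub = generate_hub(n_partners=14, n_modes=3, mode_overlap=0.1, seed=5)
        hc = cluster_partner_interfaces("HUB", self._footprints_from_models(hub))
        assert hc.n_clusters == 3
        # partners in the same planted mode share a cluster label
        label_of = dict(zip(hc.partners, hc.labels))
        for p1, m1 in hub.partner_modes.items():
            for p2, m2 in hub.partner_modes.items():
                assert (label_of[p1] == label_of[p2]) == (m1 == m2)

    def test_disjoint_footprints_all_singletons(self):
        fps = {f"P{i}": frozenset(range(i * 10 + 1, i * 10 + 6)) for i in range(5)}
        hc = cluster_partner_interfaces("HUB", fps)
        assert hc.n_clusters == 5

    def test_too_few_partners_rejected(self):
        fps = {"P1": frozenset({1}), "P2": frozenset({2})}
        with pytest.raises(InsufficientDataError):
            cluster_partner_interfaces("HUB", fps)

    def test_top_cluster_fractions_arithmetic(self):
        hub1 = generate_hub(n_partners=6, n_modes=1, seed=0)
        hc1 = cluster_partner_interfaces("H1", self._footprints_from_models(hub1))
        frac = top_cluster_fractions([hc1])
        assert frac.loc[0, "fraction_rank1"] == pytest.approx(1.0)

        class Fake:
            receptor_id = "H2"
            cluster_sizes = {1: 7, 2: 4, 3: 3}
        frac2 = top_cluster_fractions([Fake()])
        assert frac2.loc[0, "fraction_rank1"] == pytest.approx(0.5)
        assert frac2.loc[0, "fraction_rank2"] == pytest.approx(4 / 14)
        assert frac2.loc[0, "fraction_rank3"] == pytest.approx(3 / 14)
        total = sum(frac2.loc[0, [f"fraction_rank{k}" for k in (1, 2, 3)]])
        assert total == pytest.approx(1.0)


class TestInterfaceFraction:
    def test_empty_set_is_zero(self):
        assert interface_fraction(100, frozenset()) == 0.0

    @pytest.mark.parametrize("n_iface,length,expected", [
        (69, 289, 0.2388), (68, 497, 0.1368), (58, 136, 0.4265), (72, 528, 0.1364),
    ])
    def test_worked_example_ratios(self, n_iface, length, expected):
        frac = interface_fraction(length, frozenset(range(1, n_iface + 1)))
        assert frac == pytest.approx(expected, abs=5e-5)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValidationError):
            interface_fraction(0, frozenset())
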