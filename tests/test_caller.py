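import random

import pytest

from hgtsieve.caller import (
    HIERARCHY_LABELS,
    TopologyCall,
    classify_topology,
    infer_donor,
    infer_transfer_depth,
    refine_and_recall,
)
from hgtsieve.phylo import read_newick

GROUPS = {
    "focal": "recipient_insect",
    "lep2": "recipient_insect",
    "bacA": "eubacterium",
    "bacB": "eubacterium",
    "bacC": "eubacterium",
    "euk1": "fungus",
    "euk2": "plant",
    "insect1": "other_insect",
    "metazoan1": "non_arthropod_metazoan",
}


def tree_of(newick):
    gt = read_newick(newick)
    gt.groups = dict(GROUPS)
    gt.species = {k: k.capitalize() + "_species" for k in GROUPS}
    return gt


class TestClassifyTopology:
    def test_prokaryote_sister_is_hgt(self):
        gt = tree_of("((focal:1,bacA:1)95:1,(bacB:1,(euk1:1,euk2:1):1):2);")
        call = classify_topology(gt, ["focal"])
        assert call.call == "hgt"
        assert call.nesting_support == 95.0
        assert call.sister_taxa == [("Baca_species", "eubacterium")]
        assert call.six_type == "A"

    def test_eukaryote_sister_is_vertical(self):
        gt = tree_of("((focal:1,insect1:1):1,(metazoan1:1,(bacA:1,bacB:1):1):2);")
        call = classify_topology(gt, ["focal"])
        assert call.call == "vertical"
        assert call.six_type == "C"

    def test_mixed_sister_is_unresolved(self):
        gt = tree_of("((focal:1,(bacA:1,euk1:1):1):1,(euk2:1,metazoan1:1):2);")
        assert classify_topology(gt, ["focal"]).call == "unresolved"

    def test_low_support_blocks_the_call(self):
        gt = tree_of("((focal:1,bacA:1)30:1,(bacB:1,(euk1:1,euk2:1):1):2);")
        call = classify_topology(gt, ["focal"], min_support=50)
        assert call.call == "unresolved"
        assert "support" in call.reason

    def test_recipient_homologs_merge_into_focal_set(self):
        # lep2 is a recipient-lineage homolog; it must not read as a eukaryote sister
        gt = tree_of("(((focal:1,lep2:1):1,bacA:1):1,(bacB:1,(euk1:1,euk2:1):1):2);")
        call = classify_topology(gt, ["focal"])
        assert call.call == "hgt"

    def test_prokaryote_clade_sister_is_type_b(self):
        gt = tree_of("((focal:1,(bacA:1,bacB:1):1):1,(euk1:1,euk2:1):2);")
        assert classify_topology(gt, ["focal"]).six_type == "B"

    def test_deep_nesting_is_type_f(self):
        gt = tree_of("(((focal:1,bacA:1):1,bacB:1):1,(bacC:1,(euk1:1,euk2:1):1):2);")
        call = classify_topology(gt, ["focal"])
        assert call.call == "hgt"
        assert call.six_type == "F"

    def test_missing_focal_id_errors(self):
        gt = tree_of("((focal:1,bacA:1):1,(euk1:1,euk2:1):2);")
        with pytest.raises(KeyError):
            classify_topology(gt, ["ghost"])

    def test_invariant_to_leaf_order_and_branch_scaling(self):
        a = tree_of("((focal:1,bacA:1):1,(bacB:1,(euk1:1,euk2:1):1):2);")
        b = tree_of("(((euk2:3,euk1:3):3,bacB:3):6,(bacA:3,focal:3):3);")
        assert classify_topology(a, ["focal"]).call == classify_topology(b, ["focal"]).call == "hgt"


class TestRefineAndRecall:
    @staticmethod
    def family(seed=0, length=240):
        """Aligned family where the recipient nests inside bacteria but many
        weak eukaryote homologs clutter the tree."""
        rng = random.Random(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"

        def mutate(s, k):
            out = list(s)
            for i in rng.sample(range(len(out)), k):
                out[i] = rng.choice(aa)
            return "".join(out)

        bact_root = "".join(rng.choice(aa) for _ in range(length))
        bacA = mutate(bact_root, 30)
        focal = mutate(bacA, 25)
        bacB = mutate(bact_root, 40)
        euk_root = mutate(bact_root, 150)
        rows = [("focal", focal), ("bacA", bacA), ("bacB", bacB)]
        groups = {"focal": "recipient_insect", "bacA": "eubacterium", "bacB": "eubacterium"}
        for i in range(6):
            rows.append((f"euk{i}", mutate(euk_root, 60)))
            groups[f"euk{i}"] = "fungus" if i % 2 else "plant"
        return rows, groups

    def test_planted_nesting_recovered_after_pruning(self):
        rows, groups = self.family()
        call = refine_and_recall("focal", rows, groups, k_per_group=2,
                                 n_bootstrap=100, seed=4)
        assert call.call == "hgt"

    def test_too_few_taxa_returns_reason(self):
        rows, groups = self.family()
        call = refine_and_recall("focal", rows[:3], {k: groups[k] for k, _ in rows[:3]},
                                 k_per_group=0, n_bootstrap=10, seed=0)
        assert call.call == "unresolved"
        assert "4 taxa" in call.reason

    def test_seed_reproducibility(self):
        rows, groups = self.family()
        c1 = refine_and_recall("focal", rows, groups, n_bootstrap=50, seed=9)
        c2 = refine_and_recall("focal", rows, groups, n_bootstrap=50, seed=9)
        assert (c1.call, c1.nesting_support) == (c2.call, c2.nesting_support)


class TestInferDonor:
    def test_single_sister_species_at_species_rank(self):
        call = TopologyCall("x", "hgt", sister_taxa=[("Listeria grayi DSM 20601", "eubacterium")])
        donor = infer_donor(call, [])
        assert donor.species == "Listeria grayi DSM 20601"
        assert donor.genus == "Listeria"
        assert donor.rank == "species"

    def test_multiple_sisters_resolve_by_blast_rank_to_genus(self):
        call = TopologyCall(
            "x", "hgt",
            sister_taxa=[
                ("Escherichia coli", "eubacterium"),
                ("Serratia proteamaculans 568", "eubacterium"),
            ],
        )
        donor = infer_donor(call, ["Serratia proteamaculans 568", "Escherichia coli"])
        assert donor.genus == "Serratia"
        assert donor.rank == "genus"
        assert donor.species is None

    def test_non_hgt_call_errors(self):
        with pytest.raises(ValueError):
            infer_donor(TopologyCall("x", "vertical"), [])


class TestTransferDepth:
    @pytest.mark.parametrize(
        "presence,expected",
        [
            ({"Bombycoidea"}, "Bombycoidea"),
            ({"Bombycoidea", "Papilionoidea", "Noctuoidea"}, "Macrolepidoptera"),
            ({"Bombycoidea", "Papilionoidea", "Noctuoidea", "Pyraloidea"}, "Obtectmera"),
            (
                {"Bombycoidea", "Papilionoidea", "Noctuoidea", "Pyraloidea", "Tortricoidea"},
                "Apoditrysia",
            ),
        ],
    )
    def test_hierarchy(self, presence, expected):
        assert infer_transfer_depth(presence) == expected

    def test_monotone_in_presence(self):
        order = {label: i for i, label in enumerate(HIERARCHY_LABELS)}
        acc = set()
        last = -1
        for sf in ["Bombycoidea", "Noctuoidea", "Pyraloidea", "Tortricoidea"]:
            acc.add(sf)
            level = order[infer_transfer_depth(acc)]
            assert level >= last, "adding a superfamily never shallows the label"
            last = level

    def test_empty_presence_errors(self):
        with pytest.raises(ValueError):
            infer_transfer_depth(set())
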