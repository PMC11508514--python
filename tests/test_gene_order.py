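import numpy as np
import pytest

import mitoscolia as m
from mitoscolia.gene_order import GeneOrder, SignedGene
from mitoscolia.simulate import apply_events, order_with_modes

from _oracles import adjacency_breakpoints


class TestAncestralReference:
    def test_packaged_constants(self, ancestral):
        assert len(ancestral) == 37
        assert ancestral.elements[0] == SignedGene("trnI", 1, 1)
        signs = {e.label: e.sign for e in ancestral}
        assert signs["nad5"] == -1
        assert signs["trnQ"] == -1
        assert ancestral.linearization_anchor == "trnI"

    def test_all_37_genes_once(self, ancestral):
        assert len(ancestral.keys()) == 37
        assert "control_region" not in ancestral.labels()


class TestExtractGeneOrder:
    def test_identity_round_trip(self, ancestral):
        g = m.simulate_mitogenome(m.SimulationConfig(seed=1, gene_order="ancestral"))
        assert m.extract_gene_order(g).to_string() == ancestral.to_string()

    def test_duplicated_trnM_kept(self, small_genome):
        order = m.extract_gene_order(small_genome)
        assert ("trnM", 1) in order.keys() and ("trnM", 2) in order.keys()

    def test_orientation_normalised_when_genome_flipped(self, small_genome):
        """A genome deposited on the opposite strand yields the same order."""
        n = len(small_genome.sequence)
        comp = str.maketrans("ACGT", "TGCA")
        flipped_feats = [
            type(f)(label=f.label, start=n - f.end, end=n - f.start,
                    strand="-" if f.strand == "+" else "+", kind=f.kind,
                    copy_index=f.copy_index)
            for f in small_genome.features
        ]
        flipped = type(small_genome)(id="flip", sequence=small_genome.sequence.translate(comp)[::-1],
                                     circular=True, features=flipped_feats)
        a = m.extract_gene_order(small_genome)
        b = m.extract_gene_order(flipped)
        assert a.to_string() == b.to_string()

    def test_no_genes_error(self):
        g = m.AnnotatedMitogenome(id="x", sequence="ACGT" * 100, circular=True, features=[])
        with pytest.raises(ValueError):
            m.extract_gene_order(g)


class TestClassifyEvents:
    def test_identity_all_conserved(self, ancestral):
        rep = m.classify_events(ancestral, ancestral)
        assert set(rep.events.values()) == {"conserved"}
        assert rep.breakpoint_count == 0

    def test_in_place_sign_flip_is_inversion(self, ancestral):
        q = apply_events(ancestral, [("inversion", "trnF", None)])
        rep = m.classify_events(q, ancestral)
        assert rep.events["trnF"] == "inversion"
        assert rep.genes_with("inversion") == ["trnF"]

    def test_moved_and_flipped_is_inverse_transposition(self, ancestral):
        # move +trnE into -trnF's old slot with its sign flipped
        dest = [e.label for e in ancestral].index("nad5") - 1
        q = apply_events(ancestral, [("inverse_transposition", "trnE", dest)])
        rep = m.classify_events(q, ancestral)
        assert rep.events["trnE"] == "inverse_transposition"

    def test_extra_and_missing(self, ancestral, scoliini_order):
        rep = m.classify_events(scoliini_order, ancestral)
        assert rep.events["trnM.2"] == "extra"
        truncated = GeneOrder("trunc", [e for e in ancestral if e.label not in {"cox1", "nad1"}])
        rep2 = m.classify_events(truncated, ancestral)
        assert rep2.events["cox1"] == "missing" and rep2.events["nad1"] == "missing"
        # every reference gene is accounted for exactly once
        assert set(rep2.events) >= {e.label for e in ancestral}

    def test_rotation_invariance(self, ancestral, scoliini_order):
        rep0 = m.classify_events(scoliini_order, ancestral)
        rotated = scoliini_order.rotated_to("cox3")
        rep1 = m.classify_events(rotated, ancestral)
        assert rep0.events == rep1.events
        assert rep0.breakpoint_count == rep1.breakpoint_count

    def test_intra_interval_move_is_shuffled(self, ancestral):
        # swap trnW with trnC-trnY inside the nad2..cox1 tRNA cluster
        labels = [e.label for e in ancestral]
        q = apply_events(ancestral, [("transposition", "trnW", labels.index("trnY"))])
        rep = m.classify_events(q, ancestral)
        assert rep.events["trnW"] == "shuffled"

    def test_disjoint_orders_error(self, ancestral):
        other = GeneOrder("o", [SignedGene("control_region", 1, 1)])
        with pytest.raises(ValueError):
            m.classify_events(other, ancestral)


class TestBreakpointDistance:
    def test_identity_zero(self, ancestral):
        assert m.breakpoint_distance(ancestral, ancestral) == 0

    @pytest.mark.parametrize("start, k", [(3, 1), (5, 4), (10, 8)])
    def test_single_segment_reversal_gives_two(self, ancestral, start, k):
        elems = list(ancestral.elements)
        elems[start:start + k] = [e.flipped() for e in reversed(elems[start:start + k])]
        rev = GeneOrder("rev", elems)
        assert m.breakpoint_distance(rev, ancestral) == 2

    def test_label_mismatch_error(self, ancestral):
        short = GeneOrder("s", list(ancestral.elements)[:-1])
        with pytest.raises(ValueError):
            m.breakpoint_distance(short, ancestral)

    def test_matches_adjacency_enumeration_on_random_permutations(self, rng):
        labels = ["cox1", "cox2", "cox3", "cob", "nad1", "trnA", "trnC", "rrnS"]
        for _ in range(50):
            perm = rng.permutation(len(labels))
            signs = rng.choice([-1, 1], size=len(labels))
            a = GeneOrder("a", [SignedGene(labels[i], 1, int(s))
                                for i, s in zip(perm, signs)])
            perm2 = rng.permutation(len(labels))
            signs2 = rng.choice([-1, 1], size=len(labels))
            b = GeneOrder("b", [SignedGene(labels[i], 1, int(s))
                                for i, s in zip(perm2, signs2)])
            assert m.breakpoint_distance(a, b) == adjacency_breakpoints(a, b)


class TestClusterModes:
    def test_tribe_archetypes(self, scoliini_order, campsomerini_order, ancestral):
        assert m.detect_cluster_modes(scoliini_order) == ("mode1", "mode3")
        assert m.detect_cluster_modes(campsomerini_order) == ("mode2", "mode4")
        assert m.detect_cluster_modes(ancestral) == ("unknown", "unknown")

    def test_reverse_complement_invariance(self, scoliini_order, campsomerini_order):
        for order in (scoliini_order, campsomerini_order):
            assert m.detect_cluster_modes(order.reverse_complement()) == \
                m.detect_cluster_modes(order)

    def test_missing_genes_give_unknown(self, scoliini_order):
        no_l2 = GeneOrder("x", [e for e in scoliini_order if e.label != "trnL2"])
        c1, c2 = m.detect_cluster_modes(no_l2)
        assert c1 == "unknown" and c2 == "mode3"
        no_nad5 = GeneOrder("y", [e for e in scoliini_order if e.label != "nad5"])
        assert m.detect_cluster_modes(no_nad5)[1] == "unknown"

    def test_figure_taxon_modes(self):
        """Generated per-tribe fixtures reproduce the study's mode table,
        including Colpa tartara patterning with Scoliini and the unknowns
        of the two short assemblies."""
        scoliini_taxa = ["Austroscolia_ruficeps", "Carinoscolia_vittifrons",
                         "Megascolia_azurea", "Scolia_sikkimensis",
                         "Scolia_superciliaris", "Scolia_sp", "Colpa_tartara"]
        campsomerini_taxa = ["Megacampsomeris_binghami", "Megacampsomeris_farrenwhitei",
                             "Megacampsomeris_prismatica", "Micromeriella_marginella",
                             "Sericocampsomeris_flavomaculata", "Phalerimeris_phalerata"]
        for taxon in scoliini_taxa:
            order = order_with_modes("mode1", "mode3", taxon)
            assert m.detect_cluster_modes(order) == ("mode1", "mode3")
        for taxon in campsomerini_taxa:
            order = order_with_modes("mode2", "mode4", taxon)
            assert m.detect_cluster_modes(order) == ("mode2", "mode4")
        # short assemblies: dropping the cluster genes degrades to unknown
        liacos = GeneOrder("Liacos_erythrosoma",
                           [e for e in order_with_modes("mode1", "mode3")
                            if e.label not in {"cox1", "cox2", "nad2", "trnL2", "trnM"}])
        assert m.detect_cluster_modes(liacos)[0] == "unknown"
        assert m.detect_cluster_modes(liacos)[1] == "mode3"


def test_order_string_round_trip(scoliini_order):
    text = scoliini_order.to_string()
    again = GeneOrder.from_string(scoliini_order.id, text)
    assert again.to_string() == text
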