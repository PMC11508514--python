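"""Synthetic mitogenomes, trees and characters for end-to-end testing.

The generator emulates the statistical structure of scoliid mitogenome
data: circular ~15-17 kb genomes carrying the 37 standard genes (plus an
optional duplicated trnM), A+T content in the 0.75-0.87 range typical of
aculeate wasps, codon-sampled protein-coding genes so codon-usage
statistics have realistic structure, gene orders derived from the
ancestral insect arrangement by explicit rearrangement events, random
rooted trees, and binary characters evolved under Mk-type Markov models.

One integer seed drives a splittable generator hierarchy
(:class:`numpy.random.SeedSequence`), so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .ancestral import CharacterMatrix, _default_prior, mk_transition_matrix
from .gene_order import GeneOrder, SignedGene, ancestral_reference
from .genomes import AnnotatedMitogenome, GeneFeature, PCG_LABELS

__all__ = [
    "SimulationConfig",
    "gene_order_preset",
    "order_with_modes",
    "apply_events",
    "simulate_mitogenome",
    "simulate_tree",
    "simulate_character",
    "simulate_clade_study",
    "StudySimulation",
]

# Typical insect mitochondrial gene lengths (bp); PCGs exclude the stop codon.
_PCG_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "cob": 1140, "nad1": 936,
    "nad2": 1026, "nad3": 351, "nad4": 1341, "nad4l": 288, "nad5": 1719,
    "nad6": 525, "atp6": 678, "atp8": 162,
}
_RRNA_LENGTHS = {"rrnS": 780, "rrnL": 1320}
_TRNA_LENGTH = 66
_STOPS = {"TAA", "TAG"}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated mitogenome (or a batch of them)."""

    seed: int = 0
    n_genomes: int = 1
    target_at: float = 0.82
    genome_length: int = 16000
    gene_order: str | GeneOrder = "ancestral"
    tree_tips: int = 12
    model_family: str = "Mk1"
    rates: tuple[float, ...] = (0.5,)
    root_state: str | None = None

    def __post_init__(self):
        if not 0.0 < self.target_at < 1.0:
            raise ValueError("target_at must be in (0, 1)")


# --- gene-order presets and edits --------------------------------------------

def _index_of(elems: list[SignedGene], label: str, copy: int = 1) -> int:
    for i, e in enumerate(elems):
        if e.key == (label, copy):
            return i
    raise ValueError(f"gene {label}.{copy} not in order")


def order_with_modes(cluster1: str | None = None, cluster2: str | None = None,
                     order_id: str = "synthetic") -> GeneOrder:
    """Ancestral-type order edited to carry the requested cluster modes.

    ``cluster1``: mode1 (trnL2-(-trnM), Scoliini-type) or mode2
    (trnM-(-trnL2), Campsomerini-type); both add the duplicate trnM.
    ``cluster2``: mode3 (trnH-nad5-(-trnE)) or mode4 (trnE-(-nad5)-(-trnH)).
    ``None`` leaves a cluster in the ancestral state.
    """
    elems = list(ancestral_reference().elements)
    if cluster1 == "mode1":
        elems.insert(_index_of(elems, "trnL2") + 1, SignedGene("trnM", 2, -1))
    elif cluster1 == "mode2":
        i = _index_of(elems, "trnL2")
        elems[i] = SignedGene("trnL2", 1, -1)
        elems.insert(i, SignedGene("trnM", 2, 1))
    elif cluster1 is not None:
        raise ValueError(f"unknown cluster-1 mode {cluster1!r}")
    if cluster2 == "mode3":
        elems.pop(_index_of(elems, "trnE"))
        i = _index_of(elems, "nad5")  # segment -nad5,-trnH -> +trnH,+nad5,-trnE
        assert elems[i + 1].key == ("trnH", 1)
        elems[i:i + 2] = [SignedGene("trnH", 1, 1), SignedGene("nad5", 1, 1),
                          SignedGene("trnE", 1, -1)]
    elif cluster2 == "mode4":
        elems.pop(_index_of(elems, "trnE"))
        elems.insert(_index_of(elems, "nad5"), SignedGene("trnE", 1, 1))
    elif cluster2 is not None:
        raise ValueError(f"unknown cluster-2 mode {cluster2!r}")
    return GeneOrder(id=order_id, elements=elems, linearization_anchor="trnI")


_PRESETS = {
    "ancestral": lambda: ancestral_reference(),
    "scoliini_like": lambda: order_with_modes("mode1", "mode3", "scoliini_like"),
    "campsomerini_like": lambda: order_with_modes("mode2", "mode4", "campsomerini_like"),
}


def gene_order_preset(name: str) -> GeneOrder:
    """Named gene-order archetypes: ancestral, scoliini_like, campsomerini_like."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


def apply_events(order: GeneOrder, events: Sequence[tuple]) -> GeneOrder:
    """Apply rearrangement events sequentially to a signed order.

    Each event is ``(type, gene, destination)`` with type one of
    ``inversion`` (destination ignored), ``transposition`` or
    ``inverse_transposition``; ``gene`` is a label or ``(label, copy)``;
    ``destination`` is the insertion index in the order after the gene is
    removed (0..n-1).
    """
    elems = list(order.elements)
    for ev in events:
        etype, gene, dest = (list(ev) + [None])[:3]
        label, copy = gene if isinstance(gene, tuple) else (gene, 1)
        i = _index_of(elems, label, copy)
        if etype == "inversion":
            elems[i] = elems[i].flipped()
        elif etype in {"transposition", "inverse_transposition"}:
            e = elems.pop(i)
            if etype == "inverse_transposition":
                e = e.flipped()
            if dest is None or not 0 <= dest <= len(elems):
                raise ValueError(f"invalid destination {dest!r} for {etype} of {label}")
            elems.insert(dest, e)
        else:
            raise ValueError(f"unknown event type {etype!r}")
    return GeneOrder(id=order.id, elements=elems,
                     linearization_anchor=order.linearization_anchor)


# --- sequence simulation ------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, target_at: float) -> str:
    p = [target_at / 2, (1 - target_at) / 2, (1 - target_at) / 2, target_at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _conditional_at(p: float) -> float:
    """Expected per-base A+T of a codon sampled base-wise at AT prob ``p``,
    conditional on the codon not being a stop (TAA, TAG)."""
    a = p / 2  # P(A) = P(T); P(G) = P(C) = (1-p)/2
    g = (1 - p) / 2
    p_taa, p_tag = a * a * a, a * a * g
    mean_at = 3 * p  # unconditional expected AT bases per codon
    cond = (mean_at - 3 * p_taa - 2 * p_tag) / (1 - p_taa - p_tag)
    return cond / 3


def _body_at_prob(target_at: float) -> float:
    """Base AT probability whose stop-conditioned codon AT equals the target."""
    from scipy.optimize import brentq

    if _conditional_at(0.999) < target_at:
        return 0.999
    return float(brentq(lambda p: _conditional_at(p) - target_at, 1e-3, 0.999))


def _random_cds(rng: np.random.Generator, n_codons: int, target_at: float) -> str:
    """ATG start + codon-sampled body (no internal stops) + TAA stop."""
    at = _body_at_prob(target_at)
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    bases = "ACGT"
    body = []
    while len(body) < n_codons - 1:
        idx = rng.choice(4, size=3, p=p)
        codon = "".join(bases[i] for i in idx)
        if codon not in _STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def simulate_mitogenome(config: SimulationConfig,
                        genome_id: str = "sim",
                        rng: np.random.Generator | None = None) -> AnnotatedMitogenome:
    """One annotated circular genome realising the configured gene order.

    PCGs have valid start/stop codons under the invertebrate mitochondrial
    code and codon-sampled bodies; tRNAs/rRNAs/spacers are drawn base by
    base; the control region fills the genome to ``genome_length``.  The
    realised A+T content matches ``target_at`` within ~0.01 in expectation.
    """
    rng = rng or np.random.default_rng(config.seed)
    order = (gene_order_preset(config.gene_order)
             if isinstance(config.gene_order, str) else config.gene_order)

    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    for e in order.elements:
        spacer = int(rng.integers(0, 12))
        if spacer:
            parts.append(_random_bases(rng, spacer, config.target_at))
            pos += spacer
        if e.label in PCG_LABELS:
            n_codons = _PCG_LENGTHS[e.label] // 3
            seq, kind = _random_cds(rng, n_codons, config.target_at), "PCG"
        elif e.label in RRNA_LENGTHS_KEYS:
            seq, kind = _random_bases(rng, _RRNA_LENGTHS[e.label], config.target_at), "rRNA"
        else:
            seq, kind = _random_bases(rng, _TRNA_LENGTH, config.target_at), "tRNA"
        if e.sign < 0:
            seq = seq.translate(_COMPLEMENT)[::-1]
        feats.append(GeneFeature(label=e.label, start=pos, end=pos + len(seq),
                                 strand="+" if e.sign > 0 else "-",
                                 kind=kind, copy_index=e.copy))
        parts.append(seq)
        pos += len(seq)

    remaining = config.genome_length - pos
    if remaining < 100:
        raise ValueError(
            f"genome_length {config.genome_length} too small for the gene complement "
            f"({pos} bp of genes and spacers plus a control region)"
        )
    feats.append(GeneFeature(label="control_region", start=pos,
                             end=pos + remaining, strand="+", kind="other"))
    parts.append(_random_bases(rng, remaining, config.target_at))
    return AnnotatedMitogenome(id=genome_id, sequence="".join(parts),
                               circular=True, features=feats)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
RRNA_LENGTHS_KEYS = set(_RRNA_LENGTHS)


# --- tree and character simulation --------------------------------------------

def simulate_tree(n_tips: int, seed: int = 0, mean_branch_length: float = 0.3,
                  labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Random rooted binary tree, uniform over labelled histories.

    Lineages are merged two at a time uniformly at random; branch lengths
    are i.i.d. exponential with the given mean.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    taxa = dendropy.TaxonNamespace()
    lineages = []
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(lbl)
        lineages.append(node)
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        lineages = [n for n in lineages if n not in (a, b)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=lineages[0])
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(mean_branch_length))
    return tree


def simulate_character(tree: dendropy.Tree, family: str = "Mk1",
                       rates=(0.5,), root_state: str | None = None,
                       seed: int = 0, alphabet: Sequence[str] = ("0", "1"),
                       n_chars: int = 1) -> dict[str, str | list[str]]:
    """Evolve discrete characters down the tree under an Mk-type model.

    The root state is drawn from the model's root prior unless fixed.
    Returns tip label -> state (or list of states when ``n_chars > 1``).
    """
    rng = np.random.default_rng(seed)
    alphabet = tuple(alphabet)
    k = len(alphabet)
    prior = _default_prior(family, rates, k)
    state_idx = {s: i for i, s in enumerate(alphabet)}

    node_states: dict[int, np.ndarray] = {}
    if root_state is None:
        root = rng.choice(k, size=n_chars, p=prior)
    else:
        root = np.full(n_chars, state_idx[root_state])
    node_states[id(tree.seed_node)] = root

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length if node.edge.length is not None else 0.0
        P = mk_transition_matrix(family, rates, t, k)
        parent = node_states[id(node.parent_node)]
        child = np.array([rng.choice(k, p=P[s]) for s in parent])
        node_states[id(node)] = child

    out: dict[str, str | list[str]] = {}
    for leaf in tree.leaf_node_iter():
        states = [alphabet[s] for s in node_states[id(leaf)]]
        out[leaf.taxon.label] = states[0] if n_chars == 1 else states
    return out


# --- end-to-end study simulation ----------------------------------------------

@dataclass
class StudySimulation:
    """A self-contained synthetic study: genomes, tree, characters, truth."""

    genomes: list[AnnotatedMitogenome]
    tree: dendropy.Tree
    matrix: CharacterMatrix
    root_modes: tuple[str, str]
    tip_modes: dict[str, tuple[str, str]] = field(default_factory=dict)


def simulate_clade_study(n_taxa: int = 12, seed: int = 0, rate: float = 0.1,
                         target_at: float = 0.82,
                         root_modes: tuple[str, str] = ("mode1", "mode3")) -> StudySimulation:
    """Simulate a two-clade study mirroring the scoliid design.

    Cluster modes evolve on a random tree under Mk1 from the given root
    modes; each tip's mitogenome is then built to carry its simulated
    modes, so gene-order extraction, mode detection and ancestral-state
    reconstruction can be validated against the generating truth.
    """
    ss = np.random.SeedSequence(seed)
    tree_seed, c1_seed, c2_seed, genome_seed = (int(s.generate_state(1)[0] % (2**31))
                                                for s in ss.spawn(4))
    tree = simulate_tree(n_taxa, seed=tree_seed)
    c1 = simulate_character(tree, "Mk1", (rate,), root_state=root_modes[0],
                            seed=c1_seed, alphabet=("mode1", "mode2"))
    c2 = simulate_character(tree, "Mk1", (rate,), root_state=root_modes[1],
                            seed=c2_seed, alphabet=("mode3", "mode4"))
    genomes = []
    tip_modes = {}
    grng = np.random.default_rng(genome_seed)
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        modes = (c1[taxon], c2[taxon])
        tip_modes[taxon] = modes
        order = order_with_modes(*modes, order_id=taxon)
        cfg = SimulationConfig(seed=seed, target_at=target_at, gene_order=order)
        genomes.append(simulate_mitogenome(cfg, genome_id=taxon, rng=grng))
    matrix = CharacterMatrix(
        taxa=sorted(tip_modes),
        characters={"cluster1": ("mode1", "mode2"), "cluster2": ("mode3", "mode4")},
        states={t: {"cluster1": m1, "cluster2": m2} for t, (m1, m2) in tip_modes.items()},
    )
    return StudySimulation(genomes=genomes, tree=tree, matrix=matrix,
                           root_modes=root_modes, tip_modes=tip_modes)
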