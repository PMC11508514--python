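"""Packaged study fixtures.

* :func:`scoliidae_tree` — the 15-taxon Chinese Scoliidae topology
  (mitogenome PCG123+RNA tree: the tribe Campsomerini sister to
  Colpa + Scoliini), without published branch lengths; a unit-length
  fallback is offered and clearly flagged.
* :func:`scoliidae_modes` — the per-taxon cluster-1/cluster-2
  rearrangement modes scored from the 15 gene orders (``?`` = missing,
  for the two short assemblies lacking the relevant genes).
"""

from importlib import resources

import dendropy

from ..ancestral import CharacterMatrix
from ..genomes import read_newick

__all__ = ["scoliidae_tree", "scoliidae_modes", "scoliidae_root_signature"]


def _path(name: str):
    return resources.files(__package__) / name


def scoliidae_tree(unit_branch_lengths: bool = True) -> dendropy.Tree:
    """The 15-taxon Scoliidae topology; unit branch lengths by default.

    The source study's branch lengths were not published, so every edge
    is set to ``default_branch_length=1.0`` when ``unit_branch_lengths``
    (the tree's ``defaulted_branch_lengths`` flag is then True).
    """
    text = _path("scoliidae_pcg123_rna.nwk").read_text()
    return read_newick(text, default_branch_length=1.0 if unit_branch_lengths else None)


def scoliidae_modes() -> CharacterMatrix:
    """Cluster-mode character matrix for the 15 Scoliidae taxa."""
    with resources.as_file(_path("scoliidae_cluster_modes.tsv")) as p:
        return CharacterMatrix.from_tsv(
            p, alphabets={"cluster1": ("mode1", "mode2"), "cluster2": ("mode3", "mode4")}
        )


def scoliidae_root_signature() -> str:
    """Node signature of the Scoliidae root in the packaged tree."""
    tree = scoliidae_tree()
    tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    return "|".join(tips)
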