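"""Reading and normalising annotated mitogenomes and trees.

Coordinates are 1-based inclusive in GenBank flat files and converted to
0-based half-open internally.  Features spanning the circular origin are
represented with ``end > len(sequence)``; :meth:`AnnotatedMitogenome.feature_sequence`
handles the wrap.  Gene names from assorted annotation dialects (MITOS,
manual GenBank submissions) are mapped onto a canonical vocabulary:
13 protein-coding genes (cox1-3, cob, nad1-6, nad4l, atp6, atp8),
22 tRNAs (trnA..trnV with trnL1/trnL2 and trnS1/trnS2 distinguished),
the two rRNAs (rrnS, rrnL) and the control region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCG_LABELS",
    "TRNA_LABELS",
    "RRNA_LABELS",
    "CANONICAL_LABELS",
    "GeneFeature",
    "AnnotatedMitogenome",
    "GeneNameAmbiguityError",
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "read_newick",
    "write_newick",
]

PCG_LABELS = frozenset(
    {"cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3", "nad4",
     "nad4l", "nad5", "nad6", "atp6", "atp8"}
)
TRNA_LABELS = frozenset(
    {"trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
     "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
     "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY"}
)
RRNA_LABELS = frozenset({"rrnS", "rrnL"})
CANONICAL_LABELS = PCG_LABELS | TRNA_LABELS | RRNA_LABELS | {"control_region"}


class GeneNameAmbiguityError(ValueError):
    """A tRNA-Leu/Ser feature lacks the information needed to pick an isotype."""


def _kind_of(label: str) -> str:
    if label in PCG_LABELS:
        return "PCG"
    if label in TRNA_LABELS:
        return "tRNA"
    if label in RRNA_LABELS:
        return "rRNA"
    return "other"


@dataclass(frozen=True)
class GeneFeature:
    """A typed, stranded gene feature on a mitogenome.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length for features wrapping the circular origin (``start`` is always
    the biological 5' end on the + strand reading).  ``copy_index`` is 1
    for the first occurrence of a label, 2 for a duplicate (the extra trnM
    of most scoliid mitogenomes), and so on.
    """

    label: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str = "other"  # PCG | tRNA | rRNA | other
    copy_index: int = 1
    raw_label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end} for {self.label}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")
        if self.kind != "other" and self.label not in CANONICAL_LABELS:
            raise ValueError(f"non-canonical label {self.label!r} with kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """A (possibly circular) mitochondrial genome with ordered gene features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            limit = 2 * n if self.circular else n
            if f.end > limit or (not self.circular and f.end > n):
                raise ValueError(
                    f"{self.id}: feature {f.label} [{f.start},{f.end}) exceeds sequence length {n}"
                )
        self.features = sorted(self.features, key=lambda f: f.start)

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Nucleotide sequence of a feature, 5'->3' on its own strand."""
        n = len(self.sequence)
        if feature.end <= n:
            s = self.sequence[feature.start:feature.end]
        else:  # wraps the circular origin
            s = self.sequence[feature.start:] + self.sequence[: feature.end - n]
        if feature.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "PCG"]


# --- gene-name normalisation -------------------------------------------------

_PCG_ALIASES = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cob": "cob", "cytb": "cob", "cyb": "cob", "cob/cytb": "cob",
    "nad1": "nad1", "nd1": "nad1", "nadh1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadh2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadh3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadh4": "nad4",
    "nad4l": "nad4l", "nd4l": "nad4l", "nadh4l": "nad4l",
    "nad5": "nad5", "nd5": "nad5", "nadh5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadh6": "nad6",
    "atp6": "atp6", "atpase6": "atp6", "atpase 6": "atp6",
    "atp8": "atp8", "atpase8": "atp8", "atpase 8": "atp8",
}

_PRODUCT_PCG_HINTS = [
    ("cytochrome c oxidase subunit iii", "cox3"),
    ("cytochrome c oxidase subunit 3", "cox3"),
    ("cytochrome c oxidase subunit ii", "cox2"),
    ("cytochrome c oxidase subunit 2", "cox2"),
    ("cytochrome c oxidase subunit i", "cox1"),
    ("cytochrome c oxidase subunit 1", "cox1"),
    ("cytochrome oxidase subunit 1", "cox1"),
    ("cytochrome b", "cob"),
    ("nadh dehydrogenase subunit 4l", "nad4l"),
    ("nadh dehydrogenase subunit 1", "nad1"),
    ("nadh dehydrogenase subunit 2", "nad2"),
    ("nadh dehydrogenase subunit 3", "nad3"),
    ("nadh dehydrogenase subunit 4", "nad4"),
    ("nadh dehydrogenase subunit 5", "nad5"),
    ("nadh dehydrogenase subunit 6", "nad6"),
    ("atp synthase f0 subunit 6", "atp6"),
    ("atp synthase f0 subunit 8", "atp8"),
]

_RRNA_ALIASES = {
    "rrns": "rrnS", "rrn12": "rrnS", "12s": "rrnS", "s-rrna": "rrnS",
    "12s rrna": "rrnS", "12s ribosomal rna": "rrnS", "small subunit ribosomal rna": "rrnS",
    "rrnl": "rrnL", "rrn16": "rrnL", "16s": "rrnL", "l-rrna": "rrnL",
    "16s rrna": "rrnL", "16s ribosomal rna": "rrnL", "large subunit ribosomal rna": "rrnL",
}

_AA3_TO_TRN = {
    "ala": "trnA", "cys": "trnC", "asp": "trnD", "glu": "trnE", "phe": "trnF",
    "gly": "trnG", "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "asn": "trnN", "pro": "trnP", "gln": "trnQ", "arg": "trnR", "thr": "trnT",
    "val": "trnV", "trp": "trnW", "tyr": "trnY",
}

_CR_ALIASES = {"control region", "control_region", "d-loop", "a+t rich region", "at rich region"}

# codon-family hints that disambiguate the two Leu / Ser isotypes
_LEU1_HINTS = ("cun", "l1", "leu1", "(tag)", "ctn")
_LEU2_HINTS = ("uur", "l2", "leu2", "(taa)", "(taa)", "ttr", "uua", "tta")
_SER1_HINTS = ("agn", "s1", "ser1", "(tct)", "(gct)", "agy", "aga", "agc")
_SER2_HINTS = ("ucn", "s2", "ser2", "(tga)", "tcn", "uca")


def normalize_gene_name(raw: str, product: str = "") -> tuple[str, str]:
    """Map an annotation-dialect gene name onto the canonical vocabulary.

    Returns ``(label, kind)``.  Unknown names are preserved with
    ``kind='other'``; a tRNA-Leu/Ser without isotype information raises
    :class:`GeneNameAmbiguityError`.
    """
    if not raw and not product:
        raise ValueError("both raw name and product are empty")
    r = (raw or "").strip()
    p = (product or "").strip()
    rl, pl = r.lower(), p.lower()
    joined = f"{rl} {pl}"

    # exact canonical names pass through
    for lbl in CANONICAL_LABELS:
        if rl == lbl.lower():
            return lbl, _kind_of(lbl)

    if rl in _PCG_ALIASES:
        return _PCG_ALIASES[rl], "PCG"
    if rl in _RRNA_ALIASES or pl in _RRNA_ALIASES:
        return _RRNA_ALIASES.get(rl, _RRNA_ALIASES.get(pl)), "rRNA"
    for hint, lbl in _PRODUCT_PCG_HINTS:
        if hint in pl:
            return lbl, "PCG"
    if rl in _CR_ALIASES or pl in _CR_ALIASES:
        return "control_region", "other"

    if "trn" in rl or "trna" in joined:
        if "leu" in joined or rl.startswith("trnl"):
            if any(h in joined for h in _LEU1_HINTS):
                return "trnL1", "tRNA"
            if any(h in joined for h in _LEU2_HINTS):
                return "trnL2", "tRNA"
            raise GeneNameAmbiguityError(
                f"tRNA-Leu feature {raw!r}/{product!r} lacks isotype information (need UUR/CUN or L1/L2)"
            )
        if "ser" in joined or rl.startswith("trns"):
            if any(h in joined for h in _SER1_HINTS):
                return "trnS1", "tRNA"
            if any(h in joined for h in _SER2_HINTS):
                return "trnS2", "tRNA"
            raise GeneNameAmbiguityError(
                f"tRNA-Ser feature {raw!r}/{product!r} lacks isotype information (need AGN/UCN or S1/S2)"
            )
        for aa3, lbl in _AA3_TO_TRN.items():
            if aa3 in joined:
                return lbl, "tRNA"
        # single-letter MITOS style: trnA, trnW...
        if len(rl) == 4 and rl.startswith("trn"):
            cand = "trn" + r[-1].upper()
            if cand in TRNA_LABELS:
                return cand, "tRNA"

    if "ribosomal" in pl:
        if "12" in joined or "small" in pl:
            return "rrnS", "rRNA"
        if "16" in joined or "large" in pl:
            return "rrnL", "rRNA"

    return (r or p), "other"


# --- GenBank I/O --------------------------------------------------------------

_GB_KINDS = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def read_genbank(path: str | Path) -> list[AnnotatedMitogenome]:
    """Parse a GenBank flat file into :class:`AnnotatedMitogenome` records."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"could not parse {path} as GenBank: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records found in {path}")

    genomes = []
    for rec in records:
        circular = rec.annotations.get("topology", "circular") == "circular"
        n = len(rec.seq)
        feats: list[GeneFeature] = []
        for ft in rec.features:
            if ft.type not in _GB_KINDS:
                continue
            quals = ft.qualifiers
            raw = (quals.get("gene") or quals.get("label") or [""])[0]
            product = (quals.get("product") or quals.get("note") or [""])[0]
            if ft.type == "D-loop":
                raw = raw or "control_region"
            if ft.type == "misc_feature" and "control" not in (raw + product).lower() and \
                    "a+t" not in (raw + product).lower():
                continue
            if not raw and not product:
                continue
            label, kind = normalize_gene_name(raw, product)
            parts = sorted(ft.location.parts, key=lambda p: int(p.start))
            start = int(parts[0].start)
            end = int(parts[-1].end)
            if len(parts) > 1 and circular and int(parts[0].start) > int(parts[-1].end):
                # split location wrapping the origin: 5' part comes last in coords
                start = int(parts[-1].start) if ft.location.strand != -1 else int(parts[0].start)
                start = min(int(p.start) for p in parts if int(p.end) == n) \
                    if any(int(p.end) == n for p in parts) else start
                end = start + sum(len(p) for p in parts)
            strand = "-" if ft.location.strand == -1 else "+"
            feats.append(GeneFeature(label=label, start=start, end=end, strand=strand,
                                     kind=kind, raw_label=raw or product))
        if not feats:
            warnings.warn(f"record {rec.id} has no gene features; retained", stacklevel=2)
        feats.sort(key=lambda f: f.start)
        seen: dict[str, int] = {}
        numbered = []
        for f in feats:
            seen[f.label] = seen.get(f.label, 0) + 1
            numbered.append(GeneFeature(label=f.label, start=f.start, end=f.end,
                                        strand=f.strand, kind=f.kind,
                                        copy_index=seen[f.label], raw_label=f.raw_label))
        genomes.append(AnnotatedMitogenome(id=rec.id or rec.name, sequence=str(rec.seq),
                                           circular=circular, features=numbered))
    return genomes


_PRODUCT_OF = {
    "cox1": "cytochrome c oxidase subunit 1", "cox2": "cytochrome c oxidase subunit 2",
    "cox3": "cytochrome c oxidase subunit 3", "cob": "cytochrome b",
    "nad1": "NADH dehydrogenase subunit 1", "nad2": "NADH dehydrogenase subunit 2",
    "nad3": "NADH dehydrogenase subunit 3", "nad4": "NADH dehydrogenase subunit 4",
    "nad4l": "NADH dehydrogenase subunit 4L", "nad5": "NADH dehydrogenase subunit 5",
    "nad6": "NADH dehydrogenase subunit 6", "atp6": "ATP synthase F0 subunit 6",
    "atp8": "ATP synthase F0 subunit 8",
}
_TRN_PRODUCT = {
    "trnL1": "tRNA-Leu (CUN)", "trnL2": "tRNA-Leu (UUR)",
    "trnS1": "tRNA-Ser (AGN)", "trnS2": "tRNA-Ser (UCN)",
}
_AA_OF = {v: k.capitalize() for k, v in _AA3_TO_TRN.items()}


def write_genbank(genomes: Iterable[AnnotatedMitogenome], path: str | Path) -> None:
    """Write genomes as a GenBank flat file (the inverse of :func:`read_genbank`)."""
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16], description="mitochondrion")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        for f in g.features:
            loc = FeatureLocation(f.start, min(f.end, len(g.sequence)),
                                  strand=-1 if f.strand == "-" else 1)
            if f.kind == "PCG":
                ftype, product = "CDS", _PRODUCT_OF[f.label]
            elif f.kind == "tRNA":
                ftype = "tRNA"
                product = _TRN_PRODUCT.get(f.label, f"tRNA-{_AA_OF.get(f.label, f.label[-1])}")
            elif f.kind == "rRNA":
                ftype = "rRNA"
                product = "12S ribosomal RNA" if f.label == "rrnS" else "16S ribosomal RNA"
            elif f.label == "control_region":
                ftype, product = "D-loop", "control region"
            else:
                ftype, product = "misc_feature", f.raw_label or f.label
            quals = {"gene": [f.label], "product": [product]}
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


# --- newick I/O ---------------------------------------------------------------

def read_newick(source: str | Path, default_branch_length: float | None = None) -> dendropy.Tree:
    """Read a rooted newick tree.

    ``source`` may be a path or a newick string.  Missing branch lengths are
    replaced by ``default_branch_length`` when given; the tree is annotated
    with ``defaulted_branch_lengths`` and ``trifurcating_root`` flags.
    """
    s = str(source)
    if isinstance(source, Path):
        text = source.read_text()
    elif "(" in s or ";" in s:  # a newick string, not a path
        text = s
    else:
        text = Path(s).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=False,
                                 preserve_underscores=True, rooting="force-rooted")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    defaulted = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if default_branch_length is not None:
                edge.length = float(default_branch_length)
                defaulted = True
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    tree.defaulted_branch_lengths = defaulted
    tree.trifurcating_root = len(tree.seed_node.child_nodes()) == 3
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to newick; writes to ``path`` when given."""
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
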