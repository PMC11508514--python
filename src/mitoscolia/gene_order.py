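"""Signed gene orders and rearrangement classification.

A mitochondrial gene order is modelled as a circular signed permutation
with duplicates allowed (scoliid genomes typically carry an extra trnM).
Orders are compared against the ancestral insect arrangement (the
*Drosophila*-type order) by finding a maximum-length common signed
subsequence — the *anchor set* of conserved genes — and classifying each
remaining gene as an inversion (sign flipped in place), transposition
(moved, same sign; sub-labelled *shuffled* when the move stays between
the same flanking PCG/rRNA genes), or inverse transposition (moved and
flipped).

Two short signed blocks distinguish the scoliid tribes:

* cluster 1, the trnL2/trnM block: mode 1 = ``trnL2-(-trnM)``
  (Scoliini), mode 2 = ``trnM-(-trnL2)`` (Campsomerini);
* cluster 2, the trnH/nad5/trnE block: mode 3 = ``trnH-nad5-(-trnE)``
  (Scoliini), mode 4 = ``trnE-(-nad5)-(-trnH)`` (Campsomerini).

Within each cluster the two modes are reverse complements of one another,
so they are only distinguishable in a fixed reading frame: orders are
orientation-normalised (majority of PCGs on the + strand) before pattern
matching, which makes detection invariant under reverse-complementing the
whole genome while keeping the modes distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .genomes import AnnotatedMitogenome, PCG_LABELS, RRNA_LABELS

__all__ = [
    "SignedGene",
    "GeneOrder",
    "RearrangementReport",
    "CLUSTER_PATTERNS",
    "ancestral_reference",
    "extract_gene_order",
    "classify_events",
    "breakpoint_distance",
    "detect_cluster_modes",
]

_HEAVY = PCG_LABELS | RRNA_LABELS


class SignedGene(NamedTuple):
    """One element of a signed gene order."""

    label: str
    copy: int
    sign: int  # +1 or -1

    @property
    def key(self) -> tuple[str, int]:
        return (self.label, self.copy)

    def flipped(self) -> "SignedGene":
        return SignedGene(self.label, self.copy, -self.sign)

    def __str__(self) -> str:  # e.g. "-trnM.2"
        name = self.label if self.copy == 1 else f"{self.label}.{self.copy}"
        return name if self.sign > 0 else f"-{name}"


def _parse_signed(token: str) -> SignedGene:
    token = token.strip()
    sign = 1
    if token.startswith("-"):
        sign, token = -1, token[1:]
    elif token.startswith("+"):
        token = token[1:]
    label, _, copy = token.partition(".")
    return SignedGene(label, int(copy) if copy else 1, sign)


@dataclass
class GeneOrder:
    """A circular signed gene order, linearised at ``linearization_anchor``."""

    id: str
    elements: list[SignedGene]
    linearization_anchor: str = ""

    def __post_init__(self):
        if not self.elements:
            raise ValueError(f"{self.id}: empty gene order")
        keys = [e.key for e in self.elements]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"{self.id}: duplicate (label, copy) pairs {dupes}")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def labels(self) -> set[str]:
        return {e.label for e in self.elements}

    def keys(self) -> set[tuple[str, int]]:
        return {e.key for e in self.elements}

    def reverse_complement(self) -> "GeneOrder":
        """The same circular molecule read from the opposite strand."""
        return GeneOrder(self.id, [e.flipped() for e in reversed(self.elements)],
                         self.linearization_anchor)

    def rotated_to(self, label: str, copy: int = 1) -> "GeneOrder":
        keys = [e.key for e in self.elements]
        i = keys.index((label, copy))
        return GeneOrder(self.id, self.elements[i:] + self.elements[:i], label)

    def oriented(self) -> "GeneOrder":
        """Flip the reading direction if most PCGs are on the - strand."""
        plus = sum(1 for e in self.elements if e.label in PCG_LABELS and e.sign > 0)
        minus = sum(1 for e in self.elements if e.label in PCG_LABELS and e.sign < 0)
        return self.reverse_complement() if minus > plus else self

    @classmethod
    def from_string(cls, id: str, text: str) -> "GeneOrder":
        """Parse a comma-separated signed order such as ``trnI,-trnQ,trnM``."""
        elems = [_parse_signed(tok) for tok in text.split(",") if tok.strip()]
        return cls(id=id, elements=elems)

    def to_string(self) -> str:
        return ",".join(str(e) for e in self.elements)


_ANCESTRAL = [
    ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1), ("trnW", 1),
    ("trnC", -1), ("trnY", -1), ("cox1", 1), ("trnL2", 1), ("cox2", 1),
    ("trnK", 1), ("trnD", 1), ("atp8", 1), ("atp6", 1), ("cox3", 1),
    ("trnG", 1), ("nad3", 1), ("trnA", 1), ("trnR", 1), ("trnN", 1),
    ("trnS1", 1), ("trnE", 1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4l", -1), ("trnT", 1), ("trnP", -1), ("nad6", 1),
    ("cob", 1), ("trnS2", 1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1),
]


def ancestral_reference() -> GeneOrder:
    """The ancestral insect (Drosophila-type) arrangement, cut at trnI.

    37 genes; the control region is omitted from order comparisons.
    """
    return GeneOrder(
        id="ancestral_insect",
        elements=[SignedGene(lbl, 1, s) for lbl, s in _ANCESTRAL],
        linearization_anchor="trnI",
    )


def extract_gene_order(genome: AnnotatedMitogenome) -> GeneOrder:
    """Signed gene order of an annotated genome.

    Features are taken in genomic order, the control region and unknown
    features are dropped, the reading direction is normalised so that most
    PCGs are +, and the circular order is cut at trnI (falling back to
    cox1, then the first gene).
    """
    elems = [SignedGene(f.label, f.copy_index, -1 if f.strand == "-" else 1)
             for f in genome.features
             if f.kind in {"PCG", "tRNA", "rRNA"}]
    if not elems:
        raise ValueError(f"{genome.id}: no recognizable genes")
    order = GeneOrder(id=genome.id, elements=elems).oriented()
    for anchor in ("trnI", "cox1"):
        if (anchor, 1) in order.keys():
            return order.rotated_to(anchor)
    first = order.elements[0]
    return order.rotated_to(first.label, first.copy)


# --- anchor-set computation ---------------------------------------------------

def _lcs_matched(ref: Sequence[SignedGene], qry: Sequence[SignedGene]) -> tuple[tuple[int, int], set]:
    """Best common signed subsequence of two linear orders.

    Score is the tuple (length, number of PCGs in the subsequence); ties
    between equal-length anchor sets prefer the PCG-richer one, further
    ties resolve deterministically by DP traversal order.
    Returns (score, matched key set).
    """
    m, n = len(ref), len(qry)
    # dp[i][j]: best score using ref[i:], qry[j:]
    dp = [[(0, 0)] * (n + 1) for _ in range(m + 1)]
    for i in range(m - 1, -1, -1):
        ri = ref[i]
        row, below = dp[i], dp[i + 1]
        for j in range(n - 1, -1, -1):
            best = below[j] if below[j] >= row[j + 1] else row[j + 1]
            if ri == qry[j]:
                d = below[j + 1]
                cand = (d[0] + 1, d[1] + (1 if ri.label in PCG_LABELS else 0))
                if cand > best:
                    best = cand
            row[j] = best
    matched: set = set()
    i = j = 0
    while i < m and j < n:
        if ref[i] == qry[j]:
            d = dp[i + 1][j + 1]
            cand = (d[0] + 1, d[1] + (1 if ref[i].label in PCG_LABELS else 0))
            if cand == dp[i][j]:
                matched.add(ref[i].key)
                i += 1
                j += 1
                continue
        if dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return dp[0][0], matched


def _circular_anchor_set(ref: Sequence[SignedGene], qry: Sequence[SignedGene]) -> set:
    """Maximum common signed subsequence of two circular orders (key set).

    The reference linearisation is fixed; every rotation of the query is
    tried, which covers all circular alignments of a common subsequence.
    """
    n = len(qry)
    best_score, best_set = (-1, -1), set()
    for r in range(n):
        rot = list(qry[r:]) + list(qry[:r])
        score, matched = _lcs_matched(ref, rot)
        if score > best_score:
            best_score, best_set = score, matched
            if score[0] == min(len(ref), n):  # everything matched
                break
    return best_set


def _neighbors(seq: Sequence[SignedGene], idx: int) -> tuple[tuple, tuple]:
    n = len(seq)
    return seq[(idx - 1) % n].key, seq[(idx + 1) % n].key


def _heavy_flanks(seq: Sequence[SignedGene], idx: int) -> frozenset:
    """Labels of the nearest PCG/rRNA genes on either side (circular)."""
    n = len(seq)
    pred = succ = None
    for step in range(1, n):
        e = seq[(idx - step) % n]
        if e.label in _HEAVY:
            pred = e.label
            break
    for step in range(1, n):
        e = seq[(idx + step) % n]
        if e.label in _HEAVY:
            succ = e.label
            break
    return frozenset({pred, succ})


@dataclass
class RearrangementReport:
    """Per-gene rearrangement events of a query order against a reference."""

    query_id: str
    reference_id: str
    events: dict[str, str] = field(default_factory=dict)
    breakpoint_count: int = 0
    cluster1_mode: str = "unknown"
    cluster2_mode: str = "unknown"

    def genes_with(self, event: str) -> list[str]:
        return sorted(k for k, v in self.events.items() if v == event)


def _event_key(key: tuple[str, int]) -> str:
    label, copy = key
    return label if copy == 1 else f"{label}.{copy}"


def classify_events(query: GeneOrder, reference: GeneOrder | None = None) -> RearrangementReport:
    """Classify each gene of ``query`` against ``reference`` (ancestral by default).

    Genes in the maximum common signed subsequence are *conserved*; genes
    absent from the query are *missing*, genes absent from the reference
    (duplicates) are *extra*; the rest are *inversion* (same neighbors,
    sign flipped), *inverse_transposition* (moved and flipped),
    *transposition* (moved, same sign) or its intra-interval sub-type
    *shuffled*.
    """
    if reference is None:
        reference = ancestral_reference()
    qn = query.oriented()
    common = qn.keys() & reference.keys()
    if not common:
        raise ValueError(f"{query.id} and {reference.id} share no genes")

    ref_c = [e for e in reference.elements if e.key in common]
    qry_c = [e for e in qn.elements if e.key in common]
    anchors = _circular_anchor_set(ref_c, qry_c)

    ref_idx = {e.key: i for i, e in enumerate(ref_c)}
    qry_idx = {e.key: i for i, e in enumerate(qry_c)}
    ref_sign = {e.key: e.sign for e in ref_c}
    qry_sign = {e.key: e.sign for e in qry_c}

    events: dict[str, str] = {}
    for e in reference.elements:
        if e.key not in common:
            events[_event_key(e.key)] = "missing"
    for e in qn.elements:
        if e.key not in common:
            events[_event_key(e.key)] = "extra"

    for key in sorted(common):
        name = _event_key(key)
        if key in anchors:
            events[name] = "conserved"
            continue
        same_sign = ref_sign[key] == qry_sign[key]
        same_neighbors = (_neighbors(ref_c, ref_idx[key]) == _neighbors(qry_c, qry_idx[key]))
        if not same_sign:
            events[name] = "inversion" if same_neighbors else "inverse_transposition"
        elif same_neighbors:
            events[name] = "conserved"  # anchor tie-break left it out; position unchanged
        else:
            same_interval = (_heavy_flanks(ref_c, ref_idx[key])
                             == _heavy_flanks(qry_c, qry_idx[key]))
            events[name] = "shuffled" if same_interval else "transposition"

    if len(common) >= 2:
        a = GeneOrder(qn.id, [e for e in qn.elements if e.key in common])
        b = GeneOrder(reference.id, [e for e in reference.elements if e.key in common])
        bp = breakpoint_distance(a, b)
    else:
        bp = 0
    c1, c2 = detect_cluster_modes(query)
    return RearrangementReport(query_id=query.id, reference_id=reference.id,
                               events=events, breakpoint_count=bp,
                               cluster1_mode=c1, cluster2_mode=c2)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Signed circular breakpoints: adjacencies of ``a`` absent from ``b``.

    An adjacency is an ordered signed pair of neighboring genes; it is
    conserved if ``b`` contains it in either reading direction.
    """
    if a.keys() != b.keys():
        raise ValueError("gene orders cover different gene sets")

    def adjacencies(order: GeneOrder) -> set:
        elems = order.elements
        n = len(elems)
        out = set()
        for i in range(n):
            x, y = elems[i], elems[(i + 1) % n]
            fwd = (x.key, x.sign, y.key, y.sign)
            rev = (y.key, -y.sign, x.key, -x.sign)
            out.add(min(fwd, rev))
        return out

    return len(adjacencies(a) - adjacencies(b))


# Signed block patterns, in the orientation-normalised forward reading.
# Patterns are data: swap them to adopt a different display convention.
CLUSTER_PATTERNS: dict[str, dict[str, list[tuple[str, int]]]] = {
    "cluster1": {
        "mode1": [("trnL2", 1), ("trnM", -1)],
        "mode2": [("trnM", 1), ("trnL2", -1)],
    },
    "cluster2": {
        "mode3": [("trnH", 1), ("nad5", 1), ("trnE", -1)],
        "mode4": [("trnE", 1), ("nad5", -1), ("trnH", -1)],
    },
}


def _matches_at(elems: Sequence[SignedGene], start: int,
                pattern: Sequence[tuple[str, int]]) -> bool:
    n = len(elems)
    for off, (label, sign) in enumerate(pattern):
        e = elems[(start + off) % n]
        if e.label != label or e.sign != sign:  # any copy of the label matches
            return False
    return True


def detect_cluster_modes(order: GeneOrder,
                         patterns: dict | None = None) -> tuple[str, str]:
    """(cluster-1 mode, cluster-2 mode) of an order; ``'unknown'`` when absent.

    The order is orientation-normalised first; each mode's signed block is
    then searched as a contiguous circular run in the forward reading.  A
    cluster whose genes are missing, or that matches no pattern (or,
    pathologically, more than one), is reported ``unknown``.
    """
    patterns = patterns or CLUSTER_PATTERNS
    elems = order.oriented().elements
    labels = {e.label for e in elems}
    out = []
    for cluster in sorted(patterns):
        hits = []
        for mode, pat in patterns[cluster].items():
            if not all(lbl in labels for lbl, _ in pat):
                continue
            if any(_matches_at(elems, i, pat) for i in range(len(elems))):
                hits.append(mode)
        out.append(hits[0] if len(hits) == 1 else "unknown")
    return tuple(out)  # ordered cluster1, cluster2
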