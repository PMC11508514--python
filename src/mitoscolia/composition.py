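"""Base composition, strand skews and codon usage (RSCU).

Skews follow the standard strand-asymmetry definitions,

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C),

computed on the majority strand (the strand the record stores, which in
insect mitogenomes carries most protein-coding genes).  RSCU is a codon's
observed count divided by its expected count under uniform usage within
its synonymous family; families follow the invertebrate mitochondrial
genetic code (NCBI translation table 5) by default, under which e.g. Ser
has an eight-codon family (UCN + AGN) and AUA encodes Met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable

from .genomes import AnnotatedMitogenome

__all__ = [
    "CompositionSummary",
    "CodonUsageTable",
    "base_counts",
    "skews",
    "at_content",
    "codon_counts",
    "rscu",
    "codon_families",
    "composition_table",
    "rscu_matrix",
]

_AMBIGUOUS = set("RYSWKMBDHVN")
_BASES = "ACGT"


def base_counts(sequence: str) -> dict[str, int]:
    """Tally A/C/G/T/N in a sequence (case-insensitive; IUPAC ambiguity -> N)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: 0 for b in "ACGTN"}
    for i, ch in enumerate(seq):
        if ch in counts and ch != "N":
            counts[ch] += 1
        elif ch in _AMBIGUOUS:
            counts["N"] += 1
        else:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
    return counts


def skews(counts: Mapping[str, int]) -> tuple[float, float]:
    """(AT-skew, GC-skew) = ((A-T)/(A+T), (G-C)/(G+C))."""
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    if at == 0 or gc == 0:
        raise ValueError("skew undefined: A+T or G+C is zero")
    return (counts["A"] - counts["T"]) / at, (counts["G"] - counts["C"]) / gc


def at_content(counts: Mapping[str, int]) -> float:
    """(A+T)/(A+C+G+T); N is excluded from the denominator."""
    denom = sum(counts[b] for b in _BASES)
    if denom == 0:
        raise ValueError("A+T content undefined: no unambiguous bases")
    return (counts["A"] + counts["T"]) / denom


@dataclass(frozen=True)
class CompositionSummary:
    """Whole-sequence base composition with A+T content and strand skews."""

    id: str
    length: int
    counts: dict[str, int]
    at_content: float
    at_skew: float
    gc_skew: float

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "CompositionSummary":
        c = base_counts(sequence)
        at, gc = skews(c)
        return cls(id=id, length=len(sequence), counts=c,
                   at_content=at_content(c), at_skew=at, gc_skew=gc)


# --- codon usage -------------------------------------------------------------

def _dna_to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def codon_families(table_id: int = 5) -> dict[str, list[str]]:
    """Synonymous codon families (RNA alphabet) for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(_dna_to_rna(codon))
    return {aa: sorted(cs) for aa, cs in fams.items()}


@dataclass
class CodonUsageTable:
    """Per-codon counts (RNA alphabet, stop codons excluded) and RSCU values."""

    id: str
    counts: dict[str, int]
    table_id: int = 5
    warnings: list[str] = field(default_factory=list)
    rscu: dict[str, float | None] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        """Codon frequencies as fractions of the non-stop codon total."""
        tot = self.total_codons
        return {c: n / tot for c, n in self.counts.items()} if tot else {}


def codon_counts(genome: AnnotatedMitogenome, table_id: int = 5) -> CodonUsageTable:
    """Pool codon counts over all protein-coding genes of a genome.

    Each CDS is read 5'->3' on its own strand from the annotated start.
    Terminal stop codons — complete (e.g. UAA/UAG) or incomplete (a trailing
    T or TA completed by polyadenylation) — are excluded; a trailing partial
    codon that is not a recognisable incomplete stop is dropped with a
    warning, as are internal stops.
    """
    pcg_features = genome.pcgs()
    if not pcg_features:
        raise ValueError(f"{genome.id}: no protein-coding gene features")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    counts: dict[str, int] = {}
    notes: list[str] = []
    for f in pcg_features:
        cds = genome.feature_sequence(f)
        rem = len(cds) % 3
        if rem:
            tail = cds[-rem:]
            if tail not in {"T", "TA"}:
                notes.append(f"{f.label}: length not divisible by 3; dropped trailing {tail!r}")
            cds = cds[: len(cds) - rem]
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        for j, codon in enumerate(codons):
            if any(b not in _BASES for b in codon):
                notes.append(f"{f.label}: ambiguous codon {codon} skipped")
                continue
            if codon in stops:
                notes.append(f"{f.label}: internal stop {codon} at codon {j + 1}")
                continue
            rna = _dna_to_rna(codon)
            counts[rna] = counts.get(rna, 0) + 1
    for note in notes:
        warnings.warn(f"{genome.id}: {note}", stacklevel=2)
    out = CodonUsageTable(id=genome.id, counts=counts, table_id=table_id, warnings=notes)
    out.rscu = rscu(out)
    return out


def rscu(codon_table: CodonUsageTable) -> dict[str, float | None]:
    """RSCU(c) = count(c) * family_size / family_total; None when the family is unobserved."""
    fams = codon_families(codon_table.table_id)
    values: dict[str, float | None] = {}
    for codons in fams.values():
        fam_total = sum(codon_table.counts.get(c, 0) for c in codons)
        for c in codons:
            if fam_total == 0:
                values[c] = None
            else:
                values[c] = codon_table.counts.get(c, 0) * len(codons) / fam_total
    return values


# --- per-study tables --------------------------------------------------------

def composition_table(
    genomes: Iterable[AnnotatedMitogenome],
    groups: Mapping[str, str] | None = None,
    pcg_only: bool = False,
    table_id: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """One composition row per genome, plus per-group means and skew-sign counts.

    ``pcg_only`` restricts composition to the concatenated protein-coding
    genes (the per-gene-set variant reported alongside whole-record values).
    Returns ``(dataframe, summary)`` where ``summary`` carries
    ``positive_at_skew``/``negative_gc_skew`` counts and ``group_means``.
    """
    rows = []
    for g in genomes:
        if pcg_only:
            seq = "".join(g.feature_sequence(f) for f in g.pcgs())
            cs = CompositionSummary.from_sequence(g.id, seq)
        else:
            cs = CompositionSummary.from_sequence(g.id, g.sequence)
        try:
            ct = codon_counts(g, table_id=table_id)
            codon_total = ct.total_codons
        except ValueError:
            codon_total = 0
        rows.append({
            "id": g.id,
            "group": (groups or {}).get(g.id, ""),
            "length": len(g.sequence),
            **{b: cs.counts[b] for b in "ACGTN"},
            "at_content": cs.at_content,
            "at_skew": cs.at_skew,
            "gc_skew": cs.gc_skew,
            "codon_total": codon_total,
        })
    df = pd.DataFrame(rows)
    summary = {
        "positive_at_skew": int((df["at_skew"] > 0).sum()),
        "negative_gc_skew": int((df["gc_skew"] < 0).sum()),
        "group_means": (
            df[df["group"] != ""].groupby("group")["at_content"].mean().to_dict()
            if groups else {}
        ),
    }
    return df, summary


def rscu_matrix(genomes: Iterable[AnnotatedMitogenome], table_id: int = 5,
                pooled: bool = False) -> pd.DataFrame:
    """RSCU values as a codons x genomes table.

    ``pooled=True`` adds a column of RSCU computed on counts pooled over all
    genomes (the default presentation for multi-genome codon summaries).
    """
    tables = [codon_counts(g, table_id=table_id) for g in genomes]
    fams = codon_families(table_id)
    codons = [c for cs in fams.values() for c in cs]
    data = {t.id: [t.rscu.get(c) for c in codons] for t in tables}
    if pooled:
        merged: dict[str, int] = {}
        for t in tables:
            for c, n in t.counts.items():
                merged[c] = merged.get(c, 0) + n
        pooled_tab = CodonUsageTable(id="pooled", counts=merged, table_id=table_id)
        data["pooled"] = [rscu(pooled_tab).get(c) for c in codons]
    return pd.DataFrame(data, index=pd.Index(codons, name="codon")).sort_index()
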