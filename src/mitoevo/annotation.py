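"""ORF scanning and genome statistics under the mold mitochondrial code.

Fungal mitochondrial genomes use NCBI translation table 4: TGA codes for
tryptophan, so TAA and TAG are the only stops, and translation may initiate
at ATG, TTG or GTG.  The scanner reports maximal open reading frames (the
longest in-frame start per stop codon); for circular genomes the scan crosses
the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .io_formats import Feature, GenomeRecord

__all__ = [
    "OrfCall",
    "CodingStats",
    "translate_tt4",
    "find_orfs",
    "coding_statistics",
    "reverse_complement",
    "TT4_STOPS",
    "DEFAULT_STARTS",
]

TT4_STOPS = ("TAA", "TAG")
DEFAULT_STARTS = frozenset({"ATG", "TTG", "GTG"})

_TT4_FORWARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_tt4(dna: str, allow_internal: bool = False) -> str:
    """Translate an in-frame coding sequence under translation table 4.

    TGA is tryptophan; TAA/TAG stop.  A trailing stop codon is dropped from
    the protein.  An internal stop raises unless ``allow_internal`` (then it
    is rendered ``*``).  Codons containing N translate to ``X``.
    """
    dna = dna.upper()
    if len(dna) % 3:
        raise ValueError(f"sequence length {len(dna)} not a multiple of 3")
    bad = set(dna) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols {sorted(bad)!r}")
    aas: list[str] = []
    n_codons = len(dna) // 3
    for i in range(n_codons):
        codon = dna[3 * i:3 * i + 3]
        aa = _TT4_FORWARD.get(codon, "X")
        if aa == "*":
            if i == n_codons - 1:
                break  # trailing stop dropped
            if not allow_internal:
                raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class OrfCall:
    """One open reading frame; coordinates 1-based inclusive, stop included.

    On a circular genome an origin-crossing call has end < start.
    """

    start: int
    end: int
    strand: str
    frame: int
    start_codon: str
    stop_codon: str
    protein_length_aa: int

    @property
    def length_nt(self) -> int:
        return (self.protein_length_aa + 1) * 3

    def to_dict(self) -> dict:
        return {
            "start": self.start, "end": self.end, "strand": self.strand,
            "frame": self.frame, "start_codon": self.start_codon,
            "stop_codon": self.stop_codon,
            "protein_length_aa": self.protein_length_aa,
        }


def orf_sequence(genome: GenomeRecord, call: OrfCall) -> str:
    """Extract the (stop-inclusive) coding sequence of a call, unwrapping
    origin-crossing spans and reverse-complementing minus-strand calls."""
    seq = genome.sequence
    if call.strand == "+":
        if call.end >= call.start:
            sub = seq[call.start - 1:call.end]
        else:
            sub = seq[call.start - 1:] + seq[:call.end]
    else:
        if call.start >= call.end:
            sub = seq[call.end - 1:call.start]
        else:
            sub = seq[call.end - 1:] + seq[:call.start]
        sub = reverse_complement(sub)
    return sub


def _scan_strand(seq: str, L: int, circular: bool, min_length_nt: int,
                 allowed_starts: frozenset[str], strand: str,
                 report_sub_orfs: bool) -> list[OrfCall]:
    """Scan one strand of ``seq`` (already oriented 5'->3').  Positions are
    0-based offsets into the oriented sequence and mapped to genome
    coordinates afterwards."""
    work = seq + seq if circular else seq
    calls: list[OrfCall] = []
    for frame in range(3):
        starts: list[int] = []  # offsets of candidate starts since last stop
        i = frame
        while i + 3 <= len(work):
            codon = work[i:i + 3]
            if codon in TT4_STOPS:
                chosen = starts if report_sub_orfs else starts[:1]
                for s in chosen:
                    length = i + 3 - s
                    if length < min_length_nt:
                        continue
                    if circular and s >= L:
                        continue  # duplicate of a call already seen
                    if circular and length > L:
                        continue  # ORF cannot cover the genome more than once
                    calls.append(_make_call(s, i + 3, frame, work, L, strand,
                                            circular))
                starts = []
            elif codon in allowed_starts:
                starts.append(i)
            i += 3
    return calls


def _make_call(s: int, e: int, frame: int, work: str, L: int, strand: str,
               circular: bool) -> OrfCall:
    start_codon, stop_codon = work[s:s + 3], work[e - 3:e]
    protein_aa = (e - s) // 3 - 1
    # oriented coordinates (1-based on the oriented strand)
    o_start, o_end = s + 1, e
    if circular:
        o_end = (o_end - 1) % L + 1
    if strand == "+":
        g_start, g_end = o_start, o_end
    else:
        g_start, g_end = L - o_start + 1, L - o_end + 1
    return OrfCall(start=g_start, end=g_end, strand=strand, frame=frame,
                   start_codon=start_codon, stop_codon=stop_codon,
                   protein_length_aa=protein_aa)


def find_orfs(genome: GenomeRecord, min_length_nt: int = 150,
              allowed_starts: Iterable[str] = DEFAULT_STARTS,
              both_strands: bool = True,
              report_sub_orfs: bool = False) -> list[OrfCall]:
    """Find maximal ORFs: allowed start, TAA/TAG stop, no internal stop.

    For each stop codon the longest upstream in-frame start is reported;
    shorter in-frame sub-ORFs are suppressed unless ``report_sub_orfs``.
    Circular genomes are scanned across the origin (sequence logically
    doubled; calls starting beyond the original length are discarded).
    """
    if min_length_nt < 6:
        raise ValueError("min_length_nt must be >= 6 (start + stop)")
    allowed = frozenset(s.upper() for s in allowed_starts)
    L = len(genome)
    calls = _scan_strand(genome.sequence, L, genome.circular, min_length_nt,
                         allowed, "+", report_sub_orfs)
    if both_strands:
        calls += _scan_strand(reverse_complement(genome.sequence), L,
                              genome.circular, min_length_nt, allowed, "-",
                              report_sub_orfs)
    if genome.circular and not report_sub_orfs:
        # an origin-crossing ORF supersedes a shorter call onto the same stop
        best: dict[tuple[str, int], OrfCall] = {}
        for c in calls:
            key = (c.strand, c.end)
            if key not in best or c.protein_length_aa > best[key].protein_length_aa:
                best[key] = c
        calls = list(best.values())
    calls.sort(key=lambda c: (c.strand, c.start))
    return calls


# ---------------------------------------------------------------------------
# Composition / coverage statistics

@dataclass(frozen=True)
class CodingStats:
    fraction_protein: float
    fraction_trna: float
    fraction_rrna: float
    fraction_total_coding: float
    at_content: int

    def to_dict(self) -> dict:
        return {
            "fraction_protein": self.fraction_protein,
            "fraction_trna": self.fraction_trna,
            "fraction_rrna": self.fraction_rrna,
            "fraction_total_coding": self.fraction_total_coding,
            "at_content": self.at_content,
        }


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def coding_statistics(genome: GenomeRecord,
                      features: Sequence[Feature]) -> CodingStats:
    """Per-class genome coverage and AT content.

    Coverage counts each genome position once per class even when features
    overlap (union, not sum); the total is the coverage of the union of the
    protein/tRNA/rRNA classes.  Percentages are reported to one decimal;
    AT content (N excluded from the denominator) to the nearest integer,
    both rounding half up.
    """
    L = len(genome)
    class_of = {"gene_protein": 0, "orf": 0, "tRNA": 1, "rRNA": 2}
    masks = [bytearray(L) for _ in range(3)]
    for f in features:
        cls = class_of.get(f.type)
        if cls is None:
            continue
        for pos in f.positions(L):
            masks[cls][pos - 1] = 1
    covered = [sum(m) for m in masks]
    union = sum(1 for i in range(L) if masks[0][i] or masks[1][i] or masks[2][i])
    counts = {b: genome.sequence.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    at = 100.0 * (counts["A"] + counts["T"]) / denom if denom else 0.0
    return CodingStats(
        fraction_protein=_round_half_up(100.0 * covered[0] / L, 1),
        fraction_trna=_round_half_up(100.0 * covered[1] / L, 1),
        fraction_rrna=_round_half_up(100.0 * covered[2] / L, 1),
        fraction_total_coding=_round_half_up(100.0 * union / L, 1),
        at_content=int(_round_half_up(at, 0)),
    )
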