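"""Cross-species conservation screening of putative mitochondrial ORFs.

A putative ORF that truly codes for a protein should stay readable in close
relatives: orthologous regions should carry neither premature stop codons
nor net-frameshifting indels.  ``classify_orf_status`` projects a reference
ORF onto an orthologous region by pairwise alignment and assigns one status
per taxon; ``conservation_summary`` turns a panel of statuses into a
likely-coding / unlikely-coding verdict.

Status precedence when several disruptions co-occur:
absent > frameshift > premature_stop > start_lost > disrupted_by_insertion
> intact.  Frameshift is judged on the *net* indel length inside the ORF
modulo 3, so compensated indel pairs leave an ORF intact-with-indels; a long
in-frame insertion is a distinct ``disrupted_by_insertion`` class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

from .annotation import DEFAULT_STARTS, TT4_STOPS

__all__ = [
    "OrfStatus",
    "ConservationSummary",
    "classify_orf_status",
    "conservation_summary",
]

STATUS_ORDER = ("absent", "frameshift", "premature_stop", "start_lost",
                "disrupted_by_insertion", "intact")


@dataclass
class OrfStatus:
    taxon: str
    status: str
    evidence: list[tuple[int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"taxon": self.taxon, "status": self.status,
                "evidence": [list(e) for e in self.evidence]}


@dataclass
class ConservationSummary:
    orf_name: str
    n_taxa: int
    n_intact: int
    verdict: str
    transcribed: bool | None = None

    def to_dict(self) -> dict:
        return {"orf_name": self.orf_name, "n_taxa": self.n_taxa,
                "n_intact": self.n_intact, "verdict": self.verdict,
                "transcribed": self.transcribed}


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5.5
    a.extend_gap_score = -0.5
    # free end gaps on both sides: the ortholog region may extend beyond the
    # ORF, and the ORF's flanks beyond the region
    a.open_end_insertion_score = 0
    a.extend_end_insertion_score = 0
    a.open_end_deletion_score = 0
    a.extend_end_deletion_score = 0
    return a


def classify_orf_status(ref_orf_seq: str, ortholog_region: str, taxon: str,
                        flank5: str = "", flank3: str = "",
                        allowed_starts: frozenset[str] = DEFAULT_STARTS,
                        min_coverage: float = 0.5,
                        min_identity: float = 50.0,
                        insertion_flag_threshold: int = 60) -> OrfStatus:
    """Classify the state of a reference ORF inside an orthologous region.

    ``ref_orf_seq`` is the stop-inclusive reference coding sequence;
    optional flanks improve the projection at the ORF edges.  The ORF is
    projected through a semi-global pairwise alignment; alignment coverage
    of the ORF below ``min_coverage`` (or failure to align at all) gives
    ``absent``.
    """
    region = ortholog_region.upper()
    if not region:
        raise ValueError(f"taxon {taxon!r}: empty ortholog region")
    ref_orf_seq = ref_orf_seq.upper()
    if len(ref_orf_seq) % 3:
        raise ValueError("reference ORF length must be a multiple of 3")
    query = flank5.upper() + ref_orf_seq + flank3.upper()
    orf_lo, orf_hi = len(flank5), len(flank5) + len(ref_orf_seq)

    aln = _aligner().align(query, region)[0]
    q_row, r_row = str(aln[0]), str(aln[1])

    evidence: list[tuple[int, str]] = []
    q_pos = 0
    orf_len = orf_hi - orf_lo
    # region base substituting each ORF position (None where deleted)
    aligned: list[str | None] = [None] * orf_len
    # insertion runs: (orf offset after which they sit, inserted sequence)
    insert_runs: list[tuple[int, str]] = []
    cur_ins: list[str] = []

    def close_ins_run() -> None:
        if cur_ins:
            insert_runs.append((q_pos - orf_lo, "".join(cur_ins)))
            cur_ins.clear()

    for col in range(len(q_row)):
        q_c, r_c = q_row[col], r_row[col]
        if q_c == "-":
            # region base with no query counterpart: an insertion; it lies
            # in the ORF only when strictly between the ORF's query bounds
            if r_c != "-" and orf_lo < q_pos < orf_hi:
                cur_ins.append(r_c)
            continue
        close_ins_run()
        if orf_lo <= q_pos < orf_hi and r_c != "-":
            aligned[q_pos - orf_lo] = r_c
        q_pos += 1

    covered = sum(1 for b in aligned if b is not None)
    if covered / orf_len < min_coverage:
        return OrfStatus(taxon, "absent",
                         [(0, f"alignment covers {100*covered/orf_len:.0f}% "
                              "of the ORF")])
    matches = sum(1 for i, b in enumerate(aligned)
                  if b is not None and b == ref_orf_seq[i])
    if 100.0 * matches / covered < min_identity:
        return OrfStatus(taxon, "absent",
                         [(0, "region not alignable above identity cutoff")])

    n_inserted = sum(len(s) for _, s in insert_runs)
    n_deleted = sum(1 for b in aligned if b is None)
    net_indel = n_inserted - n_deleted
    if net_indel % 3 != 0:
        evidence.append((0, f"net indel length {net_indel} not a multiple of 3"))
        return OrfStatus(taxon, "frameshift", evidence)

    # premature stops, read through the reference codon frame; deleted
    # positions void their codon, inserted runs are scanned on their own
    # (large in-frame inserts are the distinct disruption class instead)
    stop_hit: tuple[int, str] | None = None
    for codon_idx in range(orf_len // 3 - 1):  # final codon = genuine stop
        bases = aligned[3 * codon_idx:3 * codon_idx + 3]
        if None in bases:
            continue
        codon = "".join(bases)  # type: ignore[arg-type]
        if codon in TT4_STOPS:
            stop_hit = (3 * codon_idx + 1, codon)
            break
    large_inframe_insert = False
    for off, ins_seq in insert_runs:
        if len(ins_seq) % 3 == 0 and len(ins_seq) >= insertion_flag_threshold:
            large_inframe_insert = True
            evidence.append((off, f"in-frame insertion of {len(ins_seq)} bp"))
        elif len(ins_seq) % 3 == 0 and stop_hit is None:
            for i in range(0, len(ins_seq), 3):
                if ins_seq[i:i + 3] in TT4_STOPS:
                    stop_hit = (off, ins_seq[i:i + 3])
                    break
    if stop_hit is not None:
        evidence.append((stop_hit[0],
                         f"in-frame stop {stop_hit[1]} before the projected "
                         "stop"))
        return OrfStatus(taxon, "premature_stop", evidence)

    start_codon = "".join(b for b in aligned[:3] if b is not None)
    if start_codon not in allowed_starts:
        evidence.append((1, f"projected start codon {start_codon!r} not in "
                            "allowed set"))
        return OrfStatus(taxon, "start_lost", evidence)

    if large_inframe_insert:
        return OrfStatus(taxon, "disrupted_by_insertion", evidence)
    return OrfStatus(taxon, "intact", evidence)


def conservation_summary(orf_name: str, statuses: Sequence[OrfStatus],
                         min_taxa: int = 4,
                         transcribed: bool | None = None
                         ) -> ConservationSummary:
    """Summarize a status panel into a coding-plausibility verdict.

    ``likely_coding`` requires every taxon intact and at least ``min_taxa``
    taxa; any premature stop, frameshift or absence gives
    ``unlikely_coding``; too few taxa gives ``insufficient``.
    """
    if not statuses:
        raise ValueError("at least one status required")
    taxa = [s.taxon for s in statuses]
    if len(taxa) != len(set(taxa)):
        raise ValueError("duplicate taxon in status panel")
    n_taxa = len(statuses)
    n_intact = sum(1 for s in statuses if s.status == "intact")
    disqualifying = any(s.status in ("premature_stop", "frameshift", "absent")
                        for s in statuses)
    if n_taxa < min_taxa:
        verdict = "insufficient"
    elif disqualifying or n_intact != n_taxa:
        verdict = "unlikely_coding"
    else:
        verdict = "likely_coding"
    return ConservationSummary(orf_name=orf_name, n_taxa=n_taxa,
                               n_intact=n_intact, verdict=verdict,
                               transcribed=transcribed)
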