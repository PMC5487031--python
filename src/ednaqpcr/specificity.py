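"""In-silico specificity screening of TaqMan primer/probe sets.

For each oligo of an assay, the scanner slides the oligo along the degapped
forward strand of a candidate sequence (the reverse primer is reverse-
complemented first, since it anneals to the sense strand) and reports the
minimum Hamming mismatch count and its leftmost position.  IUPAC ambiguity
codes are honoured on both sides: a position matches when the base sets of
the two codes intersect.  Summed over forward primer, probe and reverse
primer, the mismatch total is the assay's theoretical cross-reactivity
distance to that sequence — well-separated assays show totals of six or
more against non-target species, zero against their own target.

The module ships the four published crayfish CO1 assays (noble crayfish
*Astacus astacus*, signal crayfish *Pacifastacus leniusculus*, and
narrow-clawed crayfish *Astacus leptodactylus* clades I and III) as
:data:`REFERENCE_ASSAYS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .io_plate import GAP, AssayOligos, reverse_complement

__all__ = [
    "MismatchReport",
    "REFERENCE_ASSAYS",
    "best_window_mismatches",
    "specificity_table",
    "flag_cross_reactivity",
    "bases_match",
    "synthetic_amplicon",
]

# IUPAC code -> set of bases it stands for
_IUPAC_SET = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Published species-specific CO1 assays for European crayfish monitoring
#: (forward primer, hydrolysis probe, reverse primer, all 5'→3'; 65 bp amplicon).
REFERENCE_ASSAYS: tuple[AssayOligos, ...] = (
    AssayOligos("Astast",
                forward="GATTAGAGGAATAGTAGAGAG",
                probe="AGGAGTAGGGACAGGATGAACT",
                reverse="CTGATGCTAAAGGGGGATAA"),
    AssayOligos("Paclen",
                forward="AACTAGAGGAATAGTTGAAAG",
                probe="AGGAGTGGGTACTGGATGAACT",
                reverse="CCGCTGCTAGAGGAGGATAA"),
    AssayOligos("AstlepI",
                forward="AACTAGGGGTATAGTAGAGAG",
                probe="AGGAGTAGGGACCGGATGAACT",
                reverse="CTGATGCTAAAGGGGGATAA"),
    AssayOligos("AstlepIII",
                forward="AACTAGAGGTATAGTAGAGGG",
                probe="GGGTGTAGGAACTGGATGAACC",
                reverse="CTGATGCTAGGGGAGGATAA"),
)


@dataclass(frozen=True)
class MismatchReport:
    """Best-window mismatch counts of one assay against one sequence record.

    Windows are 0-based half-open intervals on the forward strand of the
    degapped record; each window's length equals its oligo's length.
    """

    assay_id: str
    target_record_id: str
    forward_mismatches: int
    probe_mismatches: int
    reverse_mismatches: int
    forward_window: tuple[int, int]
    probe_window: tuple[int, int]
    reverse_window: tuple[int, int]

    @property
    def total(self) -> int:
        return self.forward_mismatches + self.probe_mismatches + self.reverse_mismatches


def bases_match(oligo_code: str, record_code: str) -> bool:
    """True when the IUPAC base sets of the two codes intersect."""
    try:
        a = _IUPAC_SET[oligo_code]
        b = _IUPAC_SET[record_code]
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from exc
    return not set(a).isdisjoint(b)


def best_window_mismatches(oligo: str, record: str,
                           orientation: str = "sense") -> tuple[int, int]:
    """Minimum Hamming mismatches of ``oligo`` over all windows of ``record``.

    ``orientation="antisense"`` reverse-complements the oligo before
    scanning, so a reverse primer can be screened on the forward strand.
    Gap characters are removed from the record first.  Returns
    ``(count, leftmost position)`` on the degapped record.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be 'sense' or 'antisense', got {orientation!r}")
    query = oligo.upper()
    if orientation == "antisense":
        query = reverse_complement(query)
    target = record.upper().replace(GAP, "")
    if len(query) > len(target):
        raise ValueError(
            f"oligo ({len(query)} nt) longer than degapped record ({len(target)} nt)"
        )
    best_count, best_pos = len(query) + 1, 0
    for start in range(len(target) - len(query) + 1):
        count = 0
        for q, t in zip(query, target[start:start + len(query)]):
            if not bases_match(q, t):
                count += 1
                if count >= best_count:
                    break
        if count < best_count:
            best_count, best_pos = count, start
            if best_count == 0:
                break
    return best_count, best_pos


def specificity_table(assays: Sequence[AssayOligos],
                      records: Sequence[tuple[str, str]]) -> list[MismatchReport]:
    """Screen every assay against every record; sorted by mismatch total.

    Forward primer and probe are scanned sense, the reverse primer
    antisense.  Records shorter than an assay's longest oligo are skipped
    with a warning.
    """
    reports: list[MismatchReport] = []
    for assay in assays:
        longest = max(len(assay.forward), len(assay.probe), len(assay.reverse))
        for rec_id, seq in records:
            if len(seq.replace(GAP, "")) < longest:
                warnings.warn(
                    f"record {rec_id!r} shorter than the longest oligo of assay "
                    f"{assay.assay_id!r}; skipped",
                    stacklevel=2,
                )
                continue
            fc, fp = best_window_mismatches(assay.forward, seq, "sense")
            pc, pp = best_window_mismatches(assay.probe, seq, "sense")
            rc, rp = best_window_mismatches(assay.reverse, seq, "antisense")
            reports.append(MismatchReport(
                assay_id=assay.assay_id,
                target_record_id=rec_id,
                forward_mismatches=fc,
                probe_mismatches=pc,
                reverse_mismatches=rc,
                forward_window=(fp, fp + len(assay.forward)),
                probe_window=(pp, pp + len(assay.probe)),
                reverse_window=(rp, rp + len(assay.reverse)),
            ))
    reports.sort(key=lambda r: (r.total, r.assay_id, r.target_record_id))
    return reports


def flag_cross_reactivity(report: MismatchReport, threshold: int) -> bool:
    """Decision aid: flag a record whose mismatch total is <= ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return report.total <= threshold


def synthetic_amplicon(assay: AssayOligos, spacer: str = "TC") -> str:
    """Synthetic design-target amplicon assembled from an assay's own oligos.

    Concatenates forward primer, probe, a short spacer and the reverse
    complement of the reverse primer — a stand-in for the real target
    amplicon against which the assay has zero mismatches by construction.
    """
    return assay.forward + assay.probe + spacer + reverse_complement(assay.reverse)
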