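"""Plate-table, FASTA and results I/O plus the core domain records.

The interchange format for qPCR results is a plain CSV with one well per
row and the columns ``sample_id, assay_id, dilution_factor, ct, role``.
A well that never crossed the fluorescence threshold is a *non-detect*:
in files it is written as a configurable token (default ``"ND"``) and in
memory as ``ct=None``.  Non-detects are a distinct state throughout the
pipeline — they are never coerced to a numeric Ct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import DetectionResult

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NON_DETECT_TOKEN",
    "PLATE_COLUMNS",
    "ROLES",
    "PlateSchemaError",
    "PlateParseError",
    "SequenceAlphabetError",
    "ReplicateResult",
    "StandardPoint",
    "AssayOligos",
    "read_plate",
    "write_plate",
    "read_fasta",
    "write_results",
    "standards_from_replicates",
]

#: Default file token for a well with no amplification within the run.
NON_DETECT_TOKEN = "ND"

#: Required plate CSV header, in canonical order.
PLATE_COLUMNS = ("sample_id", "assay_id", "dilution_factor", "ct", "role")

#: Recognised well roles.
ROLES = ("unknown", "standard", "ntc", "extraction_blank", "positive_control")

# IUPAC nucleotide codes (including ambiguity codes) plus the gap character,
# so pre-made alignments can round-trip through read_fasta.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"


class PlateSchemaError(ValueError):
    """A plate table is missing a required column."""


class PlateParseError(ValueError):
    """A plate table row holds an unparseable value."""


class SequenceAlphabetError(ValueError):
    """A FASTA record contains characters outside IUPAC codes + gap."""


@dataclass(frozen=True)
class ReplicateResult:
    """One qPCR well.

    ``ct`` is the cycle threshold in cycles, or ``None`` for a non-detect.
    ``dilution_factor`` is the template dilution relative to the extract
    (1 = undiluted, 10 = ten-fold diluted).  ``censored_ct`` records the
    original Ct of a well that was administratively censored at the Ct
    cut-off; it is ``None`` for wells that were genuine non-detects.
    """

    sample_id: str
    assay_id: str
    dilution_factor: int
    ct: float | None
    role: str = "unknown"
    censored_ct: float | None = None

    def __post_init__(self) -> None:
        if self.ct is not None and not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"ct must be a finite positive number or None, got {self.ct!r}")
        if self.dilution_factor <= 0:
            raise ValueError(f"dilution_factor must be positive, got {self.dilution_factor!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass(frozen=True)
class StandardPoint:
    """Replicate Cts observed at one nominal standard concentration."""

    assay_id: str
    nominal_copies_per_reaction: float
    replicate_cts: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if self.nominal_copies_per_reaction <= 0:
            raise ValueError("nominal_copies_per_reaction must be > 0")
        if len(self.replicate_cts) == 0:
            raise ValueError("replicate_cts must be non-empty")
        object.__setattr__(self, "replicate_cts", tuple(self.replicate_cts))

    @property
    def n_detected(self) -> int:
        return sum(ct is not None for ct in self.replicate_cts)

    @property
    def n_total(self) -> int:
        return len(self.replicate_cts)


@dataclass(frozen=True)
class AssayOligos:
    """Forward primer, hydrolysis probe and reverse primer of one TaqMan assay.

    All sequences are stored 5'→3' as synthesised; the reverse primer anneals
    to the sense strand, so specificity scans use its reverse complement.
    """

    assay_id: str
    forward: str
    probe: str
    reverse: str

    def __post_init__(self) -> None:
        for name in ("forward", "probe", "reverse"):
            seq = getattr(self, name).upper()
            if len(seq) == 0:
                raise ValueError(f"{name} sequence of assay {self.assay_id!r} is empty")
            bad = set(seq) - IUPAC_CODES
            if bad:
                raise SequenceAlphabetError(
                    f"{name} sequence of assay {self.assay_id!r} has non-IUPAC "
                    f"characters: {sorted(bad)}"
                )
            object.__setattr__(self, name, seq)

    def oligos(self) -> tuple[tuple[str, str], ...]:
        return (("forward", self.forward), ("probe", self.probe), ("reverse", self.reverse))


# ---------------------------------------------------------------------------
# Plate tables
# ---------------------------------------------------------------------------

def read_plate(path: str | Path, non_detect_token: str = NON_DETECT_TOKEN) -> list[ReplicateResult]:
    """Read a plate CSV into :class:`ReplicateResult` records, row order preserved.

    Raises :class:`PlateSchemaError` when a required column is absent and
    :class:`PlateParseError` (with the data line number) when a Ct or
    dilution factor cannot be parsed.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateSchemaError(f"plate file {path} is missing column(s): {', '.join(missing)}")

    records: list[ReplicateResult] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        raw_ct = getattr(row, "ct").strip()
        if raw_ct == non_detect_token:
            ct: float | None = None
        else:
            try:
                ct = float(raw_ct)
            except ValueError as exc:
                raise PlateParseError(f"line {idx}: unparseable ct value {raw_ct!r}") from exc
        try:
            dilution = int(getattr(row, "dilution_factor"))
        except ValueError as exc:
            raise PlateParseError(
                f"line {idx}: unparseable dilution_factor "
                f"{getattr(row, 'dilution_factor')!r}"
            ) from exc
        records.append(
            ReplicateResult(
                sample_id=getattr(row, "sample_id"),
                assay_id=getattr(row, "assay_id"),
                dilution_factor=dilution,
                ct=ct,
                role=getattr(row, "role"),
            )
        )
    return records


def write_plate(
    records: Iterable[ReplicateResult],
    path: str | Path,
    non_detect_token: str = NON_DETECT_TOKEN,
) -> None:
    """Write records to the plate CSV schema (inverse of :func:`read_plate`)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "assay_id": r.assay_id,
            "dilution_factor": r.dilution_factor,
            "ct": non_detect_token if r.ct is None else repr(r.ct),
            "role": r.role,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PLATE_COLUMNS)).to_csv(path, index=False)


def standards_from_replicates(records: Sequence[ReplicateResult],
                              nominal: dict[str, float]) -> list[StandardPoint]:
    """Group standard-role wells into :class:`StandardPoint` objects.

    ``nominal`` maps each standard sample_id to its copies/reaction.
    """
    points: dict[tuple[str, str], list[float | None]] = {}
    for r in records:
        if r.role != "standard":
            continue
        points.setdefault((r.assay_id, r.sample_id), []).append(r.ct)
    out = []
    for (assay_id, sample_id), cts in points.items():
        if sample_id not in nominal:
            raise KeyError(f"no nominal copy number supplied for standard {sample_id!r}")
        out.append(StandardPoint(assay_id, nominal[sample_id], tuple(cts)))
    out.sort(key=lambda p: -p.nominal_copies_per_reaction)
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``(id, uppercased sequence)`` pairs.

    Gap characters are preserved so pre-aligned inputs survive; any character
    outside the IUPAC nucleotide codes plus ``-`` raises
    :class:`SequenceAlphabetError` naming the offending record.
    """
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_CODES - {GAP}
        if bad:
            raise SequenceAlphabetError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(results: Sequence["DetectionResult"], path: str | Path) -> None:
    """Serialize per-sample verdicts to CSV using the field reporting convention.

    A not-detected sample renders as ``0``, a detection below the limit of
    quantification as ``<LOQ`` and a quantified sample as ``mean (SD)`` in
    copies per litre, e.g. ``203 (73)``.
    """
    rows = [
        {
            "sample_id": r.sample_id,
            "assay_id": r.assay_id,
            "positive_replicates": r.positive_replicates,
            "result": r.render(),
            "copies_per_L": "" if r.copies_per_L is None else r.copies_per_L,
            "sd_copies_per_L": "" if r.sd_copies_per_L is None else r.sd_copies_per_L,
            "inhibition_flag": r.inhibition_flag,
        }
        for r in results
    ]
    columns = [
        "sample_id", "assay_id", "positive_replicates", "result",
        "copies_per_L", "sd_copies_per_L", "inhibition_flag",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
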