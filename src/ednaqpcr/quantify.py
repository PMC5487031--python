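"""Per-sample detection verdicts and copies-per-litre quantification.

Two decision schemes are implemented, mirroring the two laboratory
workflows the package supports:

* **danish** — four undiluted qPCR replicates per filter.  Detection is
  reliable only with >= 2 positive replicates; quantification requires the
  positives to sit at or above the LOQ, with non-detect replicates entering
  the mean as zero.
* **norwegian** — two undiluted plus two 10-fold-diluted replicates per
  filter.  Inhibition is assessed from ΔCt = mean(diluted) - mean(undiluted);
  the theoretical value for a clean 10× dilution is 3.32 cycles (one log10
  at ~100% efficiency) and a ±0.5-cycle window is accepted.  ΔCt below the
  window signals inhibition of the undiluted wells (quantify from diluted
  wells only); above it, the dilution is out of range (quantify from
  undiluted wells only).

Copy numbers per reaction convert to copies per litre of filtered water via

    C_L = C_r * (V_e / V_r) / V_w

with V_e the extract elution volume, V_r the template volume per reaction
and V_w the filtered water volume.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .io_plate import ReplicateResult
from .standard_curve import StandardCurve, copies_from_ct

__all__ = [
    "QuantificationContext",
    "DetectionResult",
    "SiteSummary",
    "censor_cutoff",
    "delta_ct",
    "classify_inhibition",
    "quantify_norwegian",
    "detect_danish",
    "copies_per_liter",
    "summarize_site",
]

NOT_DETECTED = "not_detected"
BELOW_LOQ = "detected_below_LOQ"
QUANTIFIED = "quantified"

INHIBITION_NONE = "none"
INHIBITED = "inhibited"
DILUTION_OUT_OF_RANGE = "dilution_out_of_range"
NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class QuantificationContext:
    """Volumes and decision thresholds for one survey protocol.

    Volumes: ``V_e`` elution volume (µL), ``V_r`` template volume per
    reaction (µL), ``V_w`` filtered water volume (L).  ``delta_ct_center``
    ± ``delta_ct_halfwidth`` is the accepted ΔCt window for an
    uninhibited 10× dilution (3.32 ± 0.5 by default).
    """

    V_e: float
    V_r: float
    V_w: float
    ct_cutoff: float = 41.0
    delta_ct_center: float = 3.32
    delta_ct_halfwidth: float = 0.5
    min_positive_replicates: int = 2
    scheme: str = "danish"

    def __post_init__(self) -> None:
        if min(self.V_e, self.V_r, self.V_w) <= 0:
            raise ValueError("all volumes must be > 0")
        if self.V_r > self.V_e:
            raise ValueError("template volume V_r cannot exceed elution volume V_e")
        if self.delta_ct_halfwidth <= 0:
            raise ValueError("delta_ct_halfwidth must be > 0")
        if self.scheme not in ("danish", "norwegian"):
            raise ValueError(f"scheme must be 'danish' or 'norwegian', got {self.scheme!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuantificationContext":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class DetectionResult:
    """Verdict for one sample/assay pair.

    ``copies_per_L`` is present exactly when ``status == "quantified"``.
    ``notes`` carries free-text audit information (e.g. which replicates a
    Norwegian estimate was based on).
    """

    sample_id: str
    assay_id: str
    status: str
    positive_replicates: str
    copies_per_L: float | None = None
    sd_copies_per_L: float | None = None
    inhibition_flag: str = NOT_ASSESSED
    notes: str = ""

    def __post_init__(self) -> None:
        if (self.copies_per_L is not None) != (self.status == QUANTIFIED):
            raise ValueError("copies_per_L must be present iff status is quantified")

    def render(self) -> str:
        """Field reporting convention: ``0``, ``<LOQ`` or ``mean (SD)``."""
        if self.status == NOT_DETECTED:
            return "0"
        if self.status == BELOW_LOQ:
            return "<LOQ"
        sd = "NA" if self.sd_copies_per_L is None else f"{self.sd_copies_per_L:.0f}"
        return f"{self.copies_per_L:.0f} ({sd})"


def censor_cutoff(reps: Sequence[ReplicateResult],
                  cutoff: float = 41.0) -> list[ReplicateResult]:
    """Censor unreliable late signals: wells with Ct >= cutoff become
    non-detects, with the original Ct retained in ``censored_ct``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    out = []
    for r in reps:
        if r.ct is not None and r.ct >= cutoff:
            out.append(replace(r, ct=None, censored_ct=r.ct))
        else:
            out.append(r)
    return out


def delta_ct(undiluted_cts: Sequence[float | None],
             diluted_cts: Sequence[float | None]) -> float:
    """ΔCt = mean(diluted) - mean(undiluted), over detected replicates only."""
    und = [ct for ct in undiluted_cts if ct is not None]
    dil = [ct for ct in diluted_cts if ct is not None]
    if not und or not dil:
        raise ValueError("ΔCt not assessable: need >= 1 detected Ct in each dilution")
    return statistics.fmean(dil) - statistics.fmean(und)


def classify_inhibition(dct: float, ctx: QuantificationContext) -> str:
    """Partition a ΔCt into inhibited / accepted / dilution-out-of-range.

    Window boundaries are inclusive: ΔCt within center ± halfwidth (2.82 to
    3.82 by default) is accepted as uninhibited.
    """
    if not math.isfinite(dct):
        raise ValueError(f"ΔCt must be finite, got {dct}")
    lo = ctx.delta_ct_center - ctx.delta_ct_halfwidth
    hi = ctx.delta_ct_center + ctx.delta_ct_halfwidth
    if dct < lo:
        return INHIBITED
    if dct > hi:
        return DILUTION_OUT_OF_RANGE
    return INHIBITION_NONE


def copies_per_liter(C_r: float, ctx: QuantificationContext) -> float:
    """C_L = C_r * (V_e / V_r) / V_w — copies per litre of filtered water."""
    if C_r < 0:
        raise ValueError(f"copies per reaction must be >= 0, got {C_r}")
    return C_r * (ctx.V_e / ctx.V_r) / ctx.V_w


def _ids(reps: Sequence[ReplicateResult]) -> tuple[str, str]:
    sample_ids = {r.sample_id for r in reps}
    assay_ids = {r.assay_id for r in reps}
    if len(sample_ids) != 1 or len(assay_ids) != 1:
        raise ValueError("replicates must belong to a single sample/assay pair")
    return sample_ids.pop(), assay_ids.pop()


def detect_danish(reps: Sequence[ReplicateResult], curve: StandardCurve,
                  lod: float, loq: float, ctx: QuantificationContext,
                  n_expected: int = 4) -> DetectionResult:
    """Replicate-majority detection rule on undiluted replicates.

    Fewer than ``min_positive_replicates`` positives → not detected.
    Quantified only when at least that many positives sit at/above the LOQ;
    non-detect replicates then enter the per-filter mean as zero copies.
    Otherwise the sample is reported as detected below LOQ.
    """
    if len(reps) != n_expected:
        raise ValueError(f"expected {n_expected} replicates, got {len(reps)}")
    sample_id, assay_id = _ids(reps)
    reps = censor_cutoff(reps, ctx.ct_cutoff)
    positives = [r for r in reps if r.detected]
    k, n = len(positives), len(reps)
    counts = f"{k}/{n}"
    if k < ctx.min_positive_replicates:
        return DetectionResult(sample_id, assay_id, NOT_DETECTED, counts,
                               inhibition_flag=NOT_ASSESSED)
    copies = [copies_from_ct(r.ct, curve) for r in positives]
    above_loq = [c for c in copies if c >= loq]
    if len(above_loq) < ctx.min_positive_replicates:
        return DetectionResult(sample_id, assay_id, BELOW_LOQ, counts,
                               inhibition_flag=NOT_ASSESSED)
    # non-detect replicates are treated as zero copies in the final mean
    per_rep_cl = [copies_per_liter(c, ctx) for c in copies] + [0.0] * (n - k)
    mean = statistics.fmean(per_rep_cl)
    sd = statistics.stdev(per_rep_cl) if len(per_rep_cl) > 1 else 0.0
    return DetectionResult(sample_id, assay_id, QUANTIFIED, counts,
                           copies_per_L=mean, sd_copies_per_L=sd,
                           inhibition_flag=NOT_ASSESSED)


def quantify_norwegian(reps: Sequence[ReplicateResult], curve: StandardCurve,
                       loq: float, ctx: QuantificationContext) -> DetectionResult:
    """Inhibition-aware quantification on a 2 undiluted + 2 diluted design.

    Per-replicate copy estimates on the undiluted-extract scale are the
    curve inversion for undiluted wells and ten times it for 10×-diluted
    wells.  The ΔCt branch selects which replicates are *relevant*:
    accepted window → all four; inhibited → diluted only; dilution out of
    range → undiluted only.  Quantified iff >= 2 relevant replicates have
    per-reaction copies at/above the LOQ; >= 2 positives otherwise report
    detected below LOQ; fewer than 2 positives report not detected (0).
    """
    undiluted = [r for r in reps if r.dilution_factor == 1]
    diluted = [r for r in reps if r.dilution_factor != 1]
    if not undiluted or not diluted:
        raise ValueError(
            "norwegian design needs both undiluted and diluted replicates per sample"
        )
    sample_id, assay_id = _ids(reps)
    undiluted = censor_cutoff(undiluted, ctx.ct_cutoff)
    diluted = censor_cutoff(diluted, ctx.ct_cutoff)
    all_reps = undiluted + diluted
    k = sum(r.detected for r in all_reps)
    counts = f"{k}/{len(all_reps)}"

    try:
        dct = delta_ct([r.ct for r in undiluted], [r.ct for r in diluted])
        flag = classify_inhibition(dct, ctx)
    except ValueError:
        flag = NOT_ASSESSED

    if flag == INHIBITED:
        relevant = diluted
    elif flag == DILUTION_OUT_OF_RANGE:
        relevant = undiluted
    else:  # accepted window, or ΔCt not assessable
        relevant = all_reps

    detected = [r for r in relevant if r.detected]
    # LOQ applies to what the reaction itself contained
    quantifiable = [r for r in detected if copies_from_ct(r.ct, curve) >= loq]
    if len(quantifiable) < ctx.min_positive_replicates:
        status = BELOW_LOQ if k >= ctx.min_positive_replicates else NOT_DETECTED
        return DetectionResult(sample_id, assay_id, status, counts, inhibition_flag=flag)

    # copies on the undiluted-extract scale: diluted wells are scaled back up
    estimates = [copies_from_ct(r.ct, curve) * r.dilution_factor for r in quantifiable]
    cl = [copies_per_liter(c, ctx) for c in estimates]
    mean = statistics.fmean(cl)
    sd = statistics.stdev(cl) if len(cl) > 1 else 0.0
    return DetectionResult(sample_id, assay_id, QUANTIFIED, counts,
                           copies_per_L=mean, sd_copies_per_L=sd,
                           inhibition_flag=flag,
                           notes=f"estimate based on {len(quantifiable)} replicates")


@dataclass(frozen=True)
class SiteSummary:
    """Across-filter summary for one site/assay."""

    site_id: str
    assay_id: str
    n_filters: int
    n_quantified: int
    mean_copies_per_L: float
    sd_copies_per_L: float
    level_grade: int
    below_loq_filters: tuple[str, ...] = field(default_factory=tuple)


def summarize_site(results: Sequence[DetectionResult],
                   site_id: str | None = None) -> SiteSummary:
    """Mean/SD of quantified copies/L across a site's filters.

    Filters that are not detected contribute zero; below-LOQ filters are
    excluded from the mean but listed in ``below_loq_filters`` (no LOQ/2
    imputation).  ``level_grade`` is a log10 bin of the mean (0 for a zero
    mean, else ``floor(log10(mean)) + 1`` clamped at 1) for coarse mapping.
    """
    if not results:
        raise ValueError("need >= 1 detection result")
    assay_ids = {r.assay_id for r in results}
    if len(assay_ids) != 1:
        raise ValueError("site summary mixes assays")
    if site_id is None:
        site_id = results[0].sample_id
    values = [r.copies_per_L for r in results if r.status == QUANTIFIED]
    values += [0.0 for r in results if r.status == NOT_DETECTED]
    below = tuple(r.sample_id for r in results if r.status == BELOW_LOQ)
    mean = statistics.fmean(values) if values else 0.0
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    grade = 0 if mean <= 0 else max(1, math.floor(math.log10(mean)) + 1)
    return SiteSummary(site_id, assay_ids.pop(), len(results),
                       sum(r.status == QUANTIFIED for r in results),
                       mean, sd, grade, below)
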