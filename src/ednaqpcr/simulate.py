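"""Synthetic qPCR plate generator.

Emulates the statistical structure the analysis modules assume, so the
whole pipeline is testable without laboratory data:

* template molecules partition into reactions as Poisson(λ) with
  λ = concentration × template volume / dilution factor;
* a reaction that receives ``k >= 1`` copies crosses the threshold at
  ``Ct = intercept + slope·log10(k) + Normal(0, sd)``, plus an additive
  inhibition shift when the template is undiluted extract;
* a reaction with zero copies — or a Ct beyond the run's cycle budget —
  is a non-detect.

Ct is generated from the *realized* copy draw, not the expectation, which
is what produces the stochastic partial detection and noisy quantification
seen near the limit of quantification.  All randomness flows through one
`numpy` generator keyed by the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_plate import ReplicateResult, StandardPoint, write_plate

__all__ = ["SimulationConfig", "SiteSpec", "simulate_reaction",
           "simulate_dilution_series", "simulate_survey"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic qPCR response.

    ``true_concentration`` is in copies/µL of extract; the default curve
    (slope -3.32 cycles/log10, intercept 40 cycles at one copy) represents
    a well-optimised TaqMan assay near 100% efficiency.  ``ct_noise_sd``
    of 0.3 cycles reproduces replicate repeatability with Ct SD below the
    ±0.5-cycle quantification bound down to ~10 copies/reaction.
    ``inhibition_shift`` (cycles) is added to undiluted wells only.
    """

    true_concentration: float = 0.0
    curve_slope: float = -3.32
    curve_intercept: float = 40.0
    ct_noise_sd: float = 0.3
    inhibition_shift: float = 0.0
    template_volume: float = 5.0
    n_replicates: int = 4
    max_cycles: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_concentration < 0:
            raise ValueError("true_concentration must be >= 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.max_cycles <= 0 or self.template_volume <= 0:
            raise ValueError("max_cycles and template_volume must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_reaction(cfg: SimulationConfig, dilution_factor: int = 1,
                      rng: np.random.Generator | None = None,
                      sample_id: str = "sim", assay_id: str = "sim",
                      role: str = "unknown") -> ReplicateResult:
    """Draw one well: Poisson copy load, then the log-linear Ct response."""
    if rng is None:
        rng = cfg.rng()
    lam = cfg.true_concentration * cfg.template_volume / dilution_factor
    k = int(rng.poisson(lam))
    ct: float | None
    if k == 0:
        ct = None
    else:
        ct = (cfg.curve_intercept + cfg.curve_slope * math.log10(k)
              + float(rng.normal(0.0, cfg.ct_noise_sd)))
        if dilution_factor == 1:
            ct += cfg.inhibition_shift
        if ct > cfg.max_cycles or ct <= 0:
            ct = None
    return ReplicateResult(sample_id=sample_id, assay_id=assay_id,
                           dilution_factor=dilution_factor, ct=ct, role=role)


def simulate_dilution_series(cfg: SimulationConfig, fold: float, n_steps: int,
                             reps_per_step: int,
                             assay_id: str = "sim") -> list[StandardPoint]:
    """Simulate a serial dilution of standards, most concentrated first.

    Step ``i`` has true concentration ``cfg.true_concentration / fold**i``
    (copies/µL); each step gets ``reps_per_step`` simulated wells.
    Reproducible for a fixed ``cfg.seed``.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    rng = cfg.rng()
    points = []
    for i in range(n_steps):
        conc = cfg.true_concentration / fold**i
        step_cfg = replace(cfg, true_concentration=conc)
        cts = tuple(
            simulate_reaction(step_cfg, dilution_factor=1, rng=rng).ct
            for _ in range(reps_per_step)
        )
        points.append(StandardPoint(assay_id, conc * cfg.template_volume, cts))
    return points


@dataclass(frozen=True)
class SiteSpec:
    """Ground truth for one simulated site/filter.

    ``true_copies_per_L`` is the eDNA concentration in the water;
    ``V_w`` (L), ``V_e`` (µL) and ``V_r`` (µL) describe filtration,
    elution and reaction loading.  ``inhibition_shift`` (cycles) applies to
    undiluted wells of this site's extract.  ``n_undiluted``/``n_diluted``
    set the replicate design (4+0 for the single-dilution scheme, 2+2 for
    the inhibition-controlled scheme).
    """

    site_id: str
    true_copies_per_L: float
    V_w: float = 5.0
    V_e: float = 200.0
    V_r: float = 2.0
    inhibition_shift: float = 0.0
    n_undiluted: int = 4
    n_diluted: int = 0

    @property
    def extract_copies_per_ul(self) -> float:
        """Extract concentration assuming complete capture and recovery."""
        return self.true_copies_per_L * self.V_w / self.V_e


def simulate_survey(sites: Sequence[SiteSpec], cfg: SimulationConfig,
                    assay_id: str = "sim", n_blanks: int = 2,
                    contamination_rate: float = 0.0,
                    plate_path: str | None = None,
                    truth_path: str | None = None,
                    ) -> tuple[list[ReplicateResult], pd.DataFrame]:
    """Simulate a multi-site survey plate with controls and a truth table.

    Returns the well records plus a per-site ground-truth DataFrame
    (``site_id, true_copies_per_L, extract_copies_per_ul, inhibition``).
    Blank/NTC wells are non-detect unless ``contamination_rate`` (the
    per-blank probability of a spurious late signal) is raised above zero.
    Optionally writes the plate CSV (readable by ``read_plate``) and the
    truth CSV.
    """
    if not (0.0 <= contamination_rate <= 1.0):
        raise ValueError("contamination_rate must be in [0, 1]")
    rng = cfg.rng()
    wells: list[ReplicateResult] = []
    truth_rows = []
    for spec in sites:
        site_cfg = replace(
            cfg,
            true_concentration=spec.extract_copies_per_ul,
            inhibition_shift=spec.inhibition_shift,
            template_volume=spec.V_r,
        )
        for dilution, count in ((1, spec.n_undiluted), (10, spec.n_diluted)):
            for _ in range(count):
                wells.append(simulate_reaction(site_cfg, dilution_factor=dilution,
                                               rng=rng, sample_id=spec.site_id,
                                               assay_id=assay_id))
        truth_rows.append({
            "site_id": spec.site_id,
            "true_copies_per_L": spec.true_copies_per_L,
            "extract_copies_per_ul": spec.extract_copies_per_ul,
            "inhibition_shift": spec.inhibition_shift,
        })
    for role, prefix in (("ntc", "NTC"), ("extraction_blank", "BLANK")):
        for i in range(n_blanks):
            ct = None
            if contamination_rate > 0 and rng.random() < contamination_rate:
                # spurious late signal typical of carry-over contamination
                ct = float(rng.uniform(41.0, cfg.max_cycles))
            wells.append(ReplicateResult(sample_id=f"{prefix}{i + 1}",
                                         assay_id=assay_id, dilution_factor=1,
                                         ct=ct, role=role))
    truth = pd.DataFrame(truth_rows)
    if plate_path is not None:
        write_plate(wells, plate_path)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    return wells, truth
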