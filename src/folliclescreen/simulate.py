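"""Synthetic screens with the statistical structure the analysis assumes.

One simulated experiment is a batch sharing a single potency perturbation
delta_e ~ Normal(0, tau) on the aspirin log-odds — emulating day-to-day
fluctuations in effective aspirin concentration (e.g. solvent evaporation) —
plus a paired wild-type control.  Each well of 20-30 follicles yields a
binomial dumped count; genotype-specific sensitivity enters as an additive
log-odds shift applied only under aspirin:

    p_vehicle  : maturation probability in vehicle medium (control: 0.92)
    p_aspirin  = logistic(logit(p_vehicle) - beta_control
                          - direction * beta_genotype + delta_e)

where beta_control is calibrated so the control matures at ~0.50 under
aspirin (dumping index ~0.50/0.92 = 0.543 before QC truncation), direction
is +1 for enhancers (more sensitive) and -1 for suppressors.

A note on variance: with 20-30 follicles per condition the binomial sampling
SD of a single control dumping index is ~0.115 — the QC band [0.4, 0.6]
truncates this to an aggregate SD of ~0.055 among *passing* controls, which
is the spread the screen's classification bands are built from.  tau
therefore contributes through the QC exclusion rate much more than through
the passing-control SD, and the calibration in :func:`calibrate_tau` targets
the QC-passing aggregate SD (the quantity the screen actually reports).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from . import scoring
from .classify import InteractorClass, classify_screen, thresholds_from_controls
from .io import ASPIRIN, VEHICLE, ScreenTable, StageTally, WellRecord
from .scoring import QC_BAND, aggregate_all, control_dumping_indices, score_screen

logger = logging.getLogger(__name__)

_P_EPS = 1e-6


class CalibrationError(ValueError):
    """The requested control-SD target is outside the achievable range."""


@dataclass(frozen=True)
class GenotypeSpec:
    """Generative parameters of one genotype.

    ``beta`` is the aspirin log-odds sensitivity shift (>= 0); ``direction``
    is +1 for an enhancer, -1 for a suppressor, 0 for a null.
    """

    label: str
    p_vehicle: float = 0.92
    beta: float = 0.0
    direction: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_vehicle <= 1.0):
            raise ValueError(f"p_vehicle must be in (0, 1], got {self.p_vehicle}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.direction not in (-1, 0, 1):
            raise ValueError(f"direction must be -1, 0 or +1, got {self.direction}")


def planted_genotype(label: str, target_di: float, p_vehicle: float = 0.92,
                     aspirin_target: float = 0.50) -> GenotypeSpec:
    """Genotype whose expected (pre-QC) dumping index equals ``target_di``.

    The planted aspirin maturation probability is target_di * p_vehicle;
    the sensitivity shift is derived on the log-odds scale relative to the
    control's aspirin response.
    """
    p_a = target_di * p_vehicle
    if not (0.0 < p_a < 1.0):
        raise ValueError(f"target_di {target_di} gives aspirin probability {p_a} outside (0,1)")
    shift = float(logit(aspirin_target) - logit(p_a))
    direction = 1 if shift > 0 else (-1 if shift < 0 else 0)
    return GenotypeSpec(label=label, p_vehicle=p_vehicle, beta=abs(shift), direction=direction)


@dataclass(frozen=True)
class SimScreenConfig:
    """Generative parameters for a synthetic screen.

    Defaults are the study conditions of the assay being emulated: wild-type
    vehicle maturation 92%, aspirin dose calibrated to 50% wild-type
    maturation, wells of 20-30 follicles, one wild-type control per
    experiment.  ``n_experiments`` is the number of *included* (QC-passing)
    replicate experiments per genotype in the "paired" layout, matching how
    replicate counts are reported for a screen: failed batches are repeated.
    """

    genotypes: tuple[GenotypeSpec, ...]
    control: GenotypeSpec = GenotypeSpec(label="yw", p_vehicle=0.92)
    aspirin_target: float = 0.50  #: control maturation probability under aspirin
    tau: float = 0.0  #: SD of the shared per-experiment aspirin log-odds jitter
    n_experiments: int = 5
    follicles_min: int = 20
    follicles_max: int = 30
    dumped_split: float = 0.5  #: P(dumped follicle scored S13/14 rather than S12)
    undumped_split: float = 0.5  #: P(undumped follicle scored S10B rather than S11)
    seed: int = 0
    layout: str = "paired"  #: "paired" (one genotype per experiment) or "pooled"
    qc_band: tuple[float, float] = QC_BAND

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not (0 < self.aspirin_target < 1):
            raise ValueError(f"aspirin_target must be in (0,1), got {self.aspirin_target}")
        if not (1 <= self.follicles_min <= self.follicles_max):
            raise ValueError("need 1 <= follicles_min <= follicles_max")
        for p in (self.dumped_split, self.undumped_split):
            if not (0.0 <= p <= 1.0):
                raise ValueError("stage-split probabilities must be in [0,1]")
        if self.layout not in ("paired", "pooled"):
            raise ValueError(f"layout must be 'paired' or 'pooled', got {self.layout!r}")

    @property
    def beta_control(self) -> float:
        """Aspirin log-odds shift of the control, from its calibration targets."""
        return float(logit(self.control.p_vehicle) - logit(self.aspirin_target))


def _clamp_p(p: float) -> float:
    if p < _P_EPS or p > 1.0 - _P_EPS:
        logger.warning("degenerate well probability %g clamped", p)
        return min(max(p, _P_EPS), 1.0 - _P_EPS)
    return p


def _aspirin_p(cfg: SimScreenConfig, g: GenotypeSpec, delta: float) -> float:
    eta = logit(g.p_vehicle) - cfg.beta_control - g.direction * g.beta + delta
    return _clamp_p(float(expit(eta)))


def _draw_wells(
    cfg: SimScreenConfig, g: GenotypeSpec, delta: float, exp_id: str, rng: np.random.Generator
) -> list[WellRecord]:
    wells = []
    for treatment in (VEHICLE, ASPIRIN):
        n = int(rng.integers(cfg.follicles_min, cfg.follicles_max + 1))
        p = _clamp_p(g.p_vehicle) if treatment == VEHICLE else _aspirin_p(cfg, g, delta)
        dumped = int(rng.binomial(n, p))
        undumped = n - dumped
        s13 = int(rng.binomial(dumped, cfg.dumped_split))
        s10b = int(rng.binomial(undumped, cfg.undumped_split))
        wells.append(
            WellRecord(
                experiment_id=exp_id,
                genotype=g.label,
                treatment=treatment,
                aspirin_mM=1.5 if treatment == ASPIRIN else 0.0,
                tally=StageTally(s10b, undumped - s10b, dumped - s13, s13),
            )
        )
    return wells


def simulate_screen(config: SimScreenConfig, rng: np.random.Generator | None = None) -> ScreenTable:
    """Generate a full screen table; fixed seed implies identical output.

    In the "paired" layout each genotype receives ``n_experiments``
    experiments of its own, each carrying a paired wild-type control; in the
    "pooled" layout there are ``n_experiments`` experiments that each contain
    every genotype plus the control.  Here ``n_experiments`` counts *drawn*
    experiments; QC filtering is downstream scoring's business (use
    :func:`recovery_experiment` for the included-replicate semantics).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[WellRecord] = []
    if config.layout == "pooled":
        for e in range(config.n_experiments):
            exp_id = f"exp{e + 1}"
            delta = float(rng.normal(0.0, config.tau)) if config.tau > 0 else 0.0
            records.extend(_draw_wells(config, config.control, delta, exp_id, rng))
            for g in config.genotypes:
                records.extend(_draw_wells(config, g, delta, exp_id, rng))
    else:
        for g in config.genotypes:
            for e in range(config.n_experiments):
                exp_id = f"{g.label}_e{e + 1}"
                delta = float(rng.normal(0.0, config.tau)) if config.tau > 0 else 0.0
                records.extend(_draw_wells(config, config.control, delta, exp_id, rng))
                records.extend(_draw_wells(config, g, delta, exp_id, rng))
    table = ScreenTable(records, control_genotype=config.control.label)
    table.validate()
    return table


# -- calibration -------------------------------------------------------------


def _control_di_sample(
    cfg: SimScreenConfig, tau: float, n_experiments: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of per-experiment control dumping indices (pre-QC)."""
    n_v = rng.integers(cfg.follicles_min, cfg.follicles_max + 1, size=n_experiments)
    n_a = rng.integers(cfg.follicles_min, cfg.follicles_max + 1, size=n_experiments)
    delta = rng.normal(0.0, tau, size=n_experiments) if tau > 0 else 0.0
    p_v = np.clip(cfg.control.p_vehicle, _P_EPS, 1 - _P_EPS)
    p_a = np.clip(
        expit(logit(cfg.control.p_vehicle) - cfg.beta_control + delta), _P_EPS, 1 - _P_EPS
    )
    f_v = rng.binomial(n_v, p_v) / n_v
    f_a = rng.binomial(n_a, p_a) / n_a
    ok = f_v > 0
    return f_a[ok] / f_v[ok]


def _qc_passing_sd(
    cfg: SimScreenConfig, tau: float, n_experiments: int, rng: np.random.Generator
) -> float:
    di = _control_di_sample(cfg, tau, n_experiments, rng)
    low, high = cfg.qc_band
    passing = di[(di >= low) & (di <= high)]
    if passing.size < 2:
        return float("nan")
    return float(passing.std(ddof=1))


def binomial_floor(config: SimScreenConfig, n_experiments: int = 20000) -> float:
    """Aggregate QC-passing control SD at tau = 0: the irreducible sampling floor."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF100E]))
    return _qc_passing_sd(config, 0.0, n_experiments, rng)


def calibrate_tau(
    target_control_sd: float,
    config: SimScreenConfig,
    rel_tol: float = 0.10,
    n_experiments: int = 20000,
    tau_max: float = 3.0,
    max_iter: int = 40,
) -> float:
    """Bisect tau so the simulated QC-passing aggregate control SD hits the target.

    The achievable SD is bounded below by the binomial sampling floor at
    tau = 0 and above by a ceiling set by QC truncation (passing indices live
    inside the QC band, so their SD cannot exceed roughly half the band
    width).  Targets outside [floor, ceiling] modulo ``rel_tol`` raise
    :class:`CalibrationError`; a target already met at tau = 0 returns 0.
    """
    if target_control_sd <= 0:
        raise CalibrationError("target SD must be positive")

    def sd_at(tau: float, salt: int) -> float:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA1, salt]))
        return _qc_passing_sd(config, tau, n_experiments, rng)

    floor = sd_at(0.0, 0)
    if target_control_sd < floor:
        if (floor - target_control_sd) / target_control_sd <= rel_tol:
            return 0.0
        raise CalibrationError(
            f"target SD {target_control_sd:g} is below the binomial sampling floor "
            f"{floor:.4f} at wells of {config.follicles_min}-{config.follicles_max} "
            "follicles: that variance is irreducible"
        )
    ceiling = sd_at(tau_max, 1)
    if target_control_sd > ceiling:
        if (target_control_sd - ceiling) / target_control_sd <= rel_tol:
            return tau_max
        raise CalibrationError(
            f"target SD {target_control_sd:g} exceeds the achievable ceiling "
            f"{ceiling:.4f}: QC truncation to {config.qc_band} caps the SD of "
            "passing control indices"
        )
    lo, hi = 0.0, tau_max
    for i in range(max_iter):
        mid = 0.5 * (lo + hi)
        sd = sd_at(mid, 2 + i)
        if abs(sd - target_control_sd) / target_control_sd <= rel_tol / 2:
            return mid
        if sd < target_control_sd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- recovery harness --------------------------------------------------------


@dataclass
class RecoveryResult:
    """Per-genotype tally of interactor calls over simulation repetitions."""

    calls: dict[str, Counter]
    n_repetitions: int

    def rate(self, genotype: str, call: str) -> float:
        if self.n_repetitions == 0:
            return float("nan")
        return self.calls[genotype][call] / self.n_repetitions

    def band_rate(self, genotype: str, band: str) -> float:
        """Fraction of repetitions whose call falls in the given band."""
        if self.n_repetitions == 0:
            return float("nan")
        total = sum(v for k, v in self.calls[genotype].items() if k.startswith(band))
        return total / self.n_repetitions


def _passing_experiment(
    cfg: SimScreenConfig, g: GenotypeSpec, exp_id: str, rng: np.random.Generator,
    max_attempts: int = 400,
) -> list[WellRecord]:
    """Draw one experiment whose control passes QC, repeating failed batches."""
    low, high = cfg.qc_band
    for _ in range(max_attempts):
        delta = float(rng.normal(0.0, cfg.tau)) if cfg.tau > 0 else 0.0
        ctrl = _draw_wells(cfg, cfg.control, delta, exp_id, rng)
        f_v = ctrl[0].tally.dumped() / ctrl[0].tally.total()
        f_a = ctrl[1].tally.dumped() / ctrl[1].tally.total()
        if f_v <= 0:
            continue
        di = f_a / f_v
        if not (low <= di <= high):
            continue
        return ctrl + _draw_wells(cfg, g, delta, exp_id, rng)
    raise RuntimeError(f"no QC-passing experiment in {max_attempts} attempts for {g.label!r}")


def simulate_included_screen(
    config: SimScreenConfig, rng: np.random.Generator | None = None
) -> ScreenTable:
    """A screen of *included* replicates: n_experiments QC-passing batches per genotype."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[WellRecord] = []
    for g in config.genotypes:
        for e in range(config.n_experiments):
            records.extend(_passing_experiment(config, g, f"{g.label}_e{e + 1}", rng))
    table = ScreenTable(records, control_genotype=config.control.label)
    table.validate()
    return table


def recovery_experiment(
    config: SimScreenConfig,
    n_repetitions: int,
    seed: int | None = None,
) -> RecoveryResult:
    """Simulate -> score -> classify repeatedly; tabulate the calls per genotype.

    Each repetition builds a screen of included replicates, derives the
    classification bands from that screen's own pooled QC-passing controls,
    and records the interactor call of every genotype.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    calls: dict[str, Counter] = {g.label: Counter() for g in config.genotypes}
    for _ in range(n_repetitions):
        table = simulate_included_screen(config, rng)
        scores = score_screen(table, config.qc_band)
        summaries = [s for s in aggregate_all(scores) if s.genotype != config.control.label]
        spec = thresholds_from_controls(
            control_dumping_indices(scores, config.control.label)
        )
        for genotype, call in classify_screen(summaries, spec):
            calls[genotype][str(call)] += 1
    return RecoveryResult(calls=calls, n_repetitions=n_repetitions)
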