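"""The screen's statistic: dumping fractions, dumping index, QC, normalization.

For each well the dumping fraction is the share of follicles that completed
nurse cell dumping (reached S12 or S13/14).  For one genotype in one
experiment the *dumping index* is the ratio of the aspirin-well fraction to
the vehicle-well fraction; the *normalized dumping index* subtracts the
same experiment's wild-type control dumping index, so batch-level potency
fluctuations cancel.  Experiments whose control dumping index falls outside
the 0.4-0.6 quality band are excluded from aggregation.

Fractions are always computed from raw counts; percentages are formatting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import ASPIRIN, VEHICLE, ScreenTable, StageTally, WellRecord

logger = logging.getLogger(__name__)

#: quality-control band on the per-experiment wild-type control dumping index;
#: an experiment is excluded when its control index is < 0.4 or > 0.6
#: (the boundaries themselves pass).
QC_BAND = (0.4, 0.6)


class EmptyWellError(ValueError):
    """A well with zero scored follicles cannot yield a fraction."""


class UndefinedIndexError(ZeroDivisionError):
    """Dumping index is undefined when no vehicle follicle matured."""


class PairingError(ValueError):
    """Scores from different experiments cannot be normalized together."""


class AggregationError(ValueError):
    """No usable replicate is available for the requested genotype."""


@dataclass(frozen=True)
class ExperimentScore:
    """One genotype within one experiment, fully scored."""

    experiment_id: str
    genotype: str
    f_control: float  #: dumping fraction in vehicle medium
    f_aspirin: float  #: dumping fraction in aspirin medium
    dumping_index: float
    normalized_index: float
    qc_pass: bool  #: carried from the experiment's wild-type control


@dataclass(frozen=True)
class GenotypeSummary:
    """Aggregate of one genotype over its QC-passing replicate experiments."""

    genotype: str
    n: int
    mean_di: float
    sd_di: float | None  #: sample SD; None when n = 1
    mean_norm: float
    sd_norm: float | None
    provisional: bool = False  #: True when n = 1
    interactor_class: object | None = None


def dumping_fraction(tally: StageTally) -> float:
    """Fraction of follicles in the well that completed dumping (S12+)."""
    total = tally.total()
    if total < 1:
        raise EmptyWellError("no follicles scored in this well")
    return tally.dumped() / total


def dumping_index(f_aspirin: float, f_control: float) -> float:
    """Ratio of aspirin-medium to vehicle-medium dumping fractions.

    Undefined (raises) when the vehicle fraction is zero: such an experiment
    is unusable, never silently 0 or infinity.
    """
    if f_control <= 0:
        raise UndefinedIndexError(
            "dumping index undefined: no follicle completed dumping in vehicle medium"
        )
    return f_aspirin / f_control


def qc_experiment(control_di: float, band: tuple[float, float] = QC_BAND) -> bool:
    """Experiment passes QC iff its control dumping index lies inside the band.

    Exclusion is phrased strictly (< low or > high), so ties at the
    boundaries pass.
    """
    low, high = band
    return low <= control_di <= high


def normalize_index(di_exp: float, di_control: float) -> float:
    """Experimental dumping index minus the same experiment's control index."""
    return di_exp - di_control


def _well_pair(wells: Sequence[WellRecord], genotype: str) -> tuple[WellRecord, WellRecord] | None:
    vehicle = aspirin = None
    for w in wells:
        if w.genotype != genotype:
            continue
        if w.treatment == VEHICLE:
            vehicle = w
        elif w.treatment == ASPIRIN:
            aspirin = w
    if vehicle is None or aspirin is None:
        return None
    return vehicle, aspirin


def score_screen(
    table: ScreenTable, qc_band: tuple[float, float] = QC_BAND
) -> list[ExperimentScore]:
    """Score every (experiment, genotype) pair of a validated screen table.

    Each experiment is anchored to its own wild-type control: the control's
    dumping index defines QC for all scores in that experiment and is the
    reference subtracted to form the normalized index.  Experiments whose
    control is missing or undefined (vehicle fraction 0) are reported and
    yield no scores.
    """
    scores: list[ExperimentScore] = []
    by_exp: dict[str, list[WellRecord]] = {}
    for r in table.records:
        by_exp.setdefault(r.experiment_id, []).append(r)
    for exp, wells in by_exp.items():
        control_pair = _well_pair(wells, table.control_genotype)
        if control_pair is None:
            logger.warning("experiment %r skipped: no complete control pair", exp)
            continue
        try:
            f_c_ctrl = dumping_fraction(control_pair[0].tally)
            f_a_ctrl = dumping_fraction(control_pair[1].tally)
            di_ctrl = dumping_index(f_a_ctrl, f_c_ctrl)
        except (EmptyWellError, UndefinedIndexError) as err:
            logger.warning("experiment %r unusable: %s", exp, err)
            continue
        qc = qc_experiment(di_ctrl, qc_band)
        genotypes: dict[str, None] = {}
        for w in wells:
            genotypes.setdefault(w.genotype, None)
        for genotype in genotypes:
            pair = _well_pair(wells, genotype)
            if pair is None:
                logger.warning(
                    "experiment %r: genotype %r lacks a treatment pair, skipped", exp, genotype
                )
                continue
            try:
                f_c = dumping_fraction(pair[0].tally)
                f_a = dumping_fraction(pair[1].tally)
                di = dumping_index(f_a, f_c)
            except (EmptyWellError, UndefinedIndexError) as err:
                logger.warning("experiment %r, genotype %r unusable: %s", exp, genotype, err)
                continue
            scores.append(
                ExperimentScore(
                    experiment_id=exp,
                    genotype=genotype,
                    f_control=f_c,
                    f_aspirin=f_a,
                    dumping_index=di,
                    normalized_index=normalize_index(di, di_ctrl),
                    qc_pass=qc,
                )
            )
    return scores


def _mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def aggregate(scores: Iterable[ExperimentScore], genotype: str) -> GenotypeSummary:
    """Mean and sample SD over the genotype's QC-passing replicates.

    ``n`` counts the QC-passing experiments only; with a single replicate the
    SDs are reported missing (not 0) and the summary is flagged provisional.
    """
    usable = [s for s in scores if s.genotype == genotype and s.qc_pass]
    if not usable:
        raise AggregationError(f"no QC-passing replicate for genotype {genotype!r}")
    dis = [s.dumping_index for s in usable]
    norms = [s.normalized_index for s in usable]
    mean_di, sd_di = _mean_sd(dis)
    mean_norm, sd_norm = _mean_sd(norms)
    return GenotypeSummary(
        genotype=genotype,
        n=len(usable),
        mean_di=mean_di,
        sd_di=sd_di,
        mean_norm=mean_norm,
        sd_norm=sd_norm,
        provisional=len(usable) == 1,
    )


def aggregate_all(scores: Sequence[ExperimentScore]) -> list[GenotypeSummary]:
    """Aggregate every genotype with at least one QC-passing replicate."""
    genotypes: dict[str, None] = {}
    for s in scores:
        genotypes.setdefault(s.genotype, None)
    out = []
    for g in genotypes:
        try:
            out.append(aggregate(scores, g))
        except AggregationError:
            logger.warning("genotype %r dropped: no QC-passing replicate", g)
    return out


def control_dumping_indices(
    scores: Iterable[ExperimentScore], control_genotype: str = "yw", qc_only: bool = True
) -> list[float]:
    """Pooled per-experiment control dumping indices (non-normalized)."""
    return [
        s.dumping_index
        for s in scores
        if s.genotype == control_genotype and (s.qc_pass or not qc_only)
    ]


def scores_to_dataframe(scores: Sequence[ExperimentScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "experiment_id": s.experiment_id,
                "genotype": s.genotype,
                "f_control": s.f_control,
                "f_aspirin": s.f_aspirin,
                "dumping_index": s.dumping_index,
                "normalized_index": s.normalized_index,
                "qc_pass": s.qc_pass,
            }
            for s in scores
        ],
        columns=[
            "experiment_id",
            "genotype",
            "f_control",
            "f_aspirin",
            "dumping_index",
            "normalized_index",
            "qc_pass",
        ],
    )


def write_scores_table(scores: Sequence[ExperimentScore], path: str | Path) -> None:
    scores_to_dataframe(scores).to_csv(path, sep="\t", index=False)
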