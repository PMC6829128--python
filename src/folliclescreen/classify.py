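"""SD-banded interactor calls from aggregate normalized dumping indices.

The classification bands are derived from the sample SD (sigma) of the
pooled, QC-passing, *non-normalized* wild-type control dumping indices:
a genotype whose mean normalized index has magnitude below sigma is a
non-interactor, between sigma and 3 sigma a weak interactor, and at or above
3 sigma a strong interactor.  Negative means are enhancers (more sensitive
to COX inhibition), positive means suppressors.

Boundary convention: the strong band is inclusive at 3 sigma and the
non-interactor band exclusive at sigma, so the partition is exhaustive.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from .scoring import GenotypeSummary

logger = logging.getLogger(__name__)


class Band(str, Enum):
    NON_INTERACTOR = "non-interactor"
    WEAK = "weak"
    STRONG = "strong"


class Direction(str, Enum):
    ENHANCER = "enhancer"
    SUPPRESSOR = "suppressor"
    NONE = "none"


@dataclass(frozen=True)
class InteractorClass:
    band: Band
    direction: Direction

    def __post_init__(self) -> None:
        if (self.band is Band.NON_INTERACTOR) != (self.direction is Direction.NONE):
            raise ValueError("direction is 'none' exactly for non-interactors")

    def __str__(self) -> str:
        if self.band is Band.NON_INTERACTOR:
            return self.band.value
        return f"{self.band.value} {self.direction.value}"


@dataclass(frozen=True)
class ThresholdSpec:
    """Classification bands derived from the aggregate control SD."""

    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma >= 0) or math.isnan(self.sigma):
            raise ValueError(f"sigma must be a non-negative real, got {self.sigma}")
        if self.sigma == 0:
            logger.warning(
                "sigma is 0: classification degenerate, every nonzero effect is 'strong'"
            )

    @property
    def weak_bound(self) -> float:
        return self.sigma

    @property
    def strong_bound(self) -> float:
        return 3.0 * self.sigma

    @classmethod
    def from_sigma(cls, sigma: float) -> "ThresholdSpec":
        return cls(sigma=float(sigma))


def thresholds_from_controls(control_dis: Sequence[float]) -> ThresholdSpec:
    """Bands from pooled QC-passing, non-normalized wild-type dumping indices.

    (The *normalized* control values are identically zero by construction and
    carry no spread, hence sigma is taken from the raw control indices.)
    """
    values = list(control_dis)
    if len(values) < 2:
        raise ValueError(
            f"need at least 2 control dumping indices for a sample SD, got {len(values)}"
        )
    mean = sum(values) / len(values)
    sigma = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
    return ThresholdSpec(sigma=sigma)


def classify(mean_norm: float, spec: ThresholdSpec) -> InteractorClass:
    """Band from the magnitude of the mean normalized index, direction from sign."""
    mag = abs(mean_norm)
    if spec.sigma == 0:
        # degenerate spec: any nonzero effect is infinitely many SDs away
        band = Band.STRONG if mag > 0 else Band.NON_INTERACTOR
    elif mag >= spec.strong_bound:
        band = Band.STRONG
    elif mag >= spec.weak_bound:
        band = Band.WEAK
    else:
        band = Band.NON_INTERACTOR
    if band is Band.NON_INTERACTOR:
        return InteractorClass(band, Direction.NONE)
    direction = Direction.ENHANCER if mean_norm < 0 else Direction.SUPPRESSOR
    return InteractorClass(band, direction)


def classify_screen(
    summaries: Sequence[GenotypeSummary],
    spec: ThresholdSpec,
    control_genotype: str | None = None,
) -> list[tuple[str, InteractorClass]]:
    """One interactor call per genotype summary.

    The control genotype, if present, is non-interactor by construction (its
    normalized index is identically zero).  Single-replicate genotypes are
    classified by the same rule; their summaries already carry the
    ``provisional`` flag.
    """
    calls: list[tuple[str, InteractorClass]] = []
    for s in summaries:
        if control_genotype is not None and s.genotype == control_genotype:
            calls.append((s.genotype, InteractorClass(Band.NON_INTERACTOR, Direction.NONE)))
        else:
            calls.append((s.genotype, classify(s.mean_norm, spec)))
    return calls


def classification_report(
    summaries: Sequence[GenotypeSummary],
    spec: ThresholdSpec,
    control_genotype: str | None = None,
    sigma_source: str = "computed",
) -> dict:
    """JSON-serializable classification report (the machine-readable chart)."""
    calls = dict(classify_screen(summaries, spec, control_genotype))
    entries = []
    for s in summaries:
        call = calls[s.genotype]
        entries.append(
            {
                "genotype": s.genotype,
                "n": s.n,
                "mean_norm": s.mean_norm,
                "sd_norm": s.sd_norm,
                "band": call.band.value,
                "direction": call.direction.value,
                "provisional": s.provisional,
            }
        )
    return {
        "thresholds": {
            "sigma": spec.sigma,
            "weak_bound": spec.weak_bound,
            "strong_bound": spec.strong_bound,
            "source": sigma_source,
        },
        "genotypes": entries,
    }


def write_classification_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
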