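"""Model/Results interface over the screen pipeline.

:class:`DumpingScreenModel` is constructed from a screen table (or a tidy
dataframe / CSV) and ``fit()`` runs scoring, QC, aggregation, threshold
derivation and interactor classification, returning a
:class:`ScreenResults` that carries the per-experiment scores, per-genotype
estimates with their uncertainties, the classification bands, and the
associated hypothesis tests.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import (
    InteractorClass,
    ThresholdSpec,
    classification_report,
    classify_screen,
    thresholds_from_controls,
)
from .inference import GroupStats, TestResult, dunnett_many_to_one, one_way_anova
from .io import ScreenTable, read_screen_table, screen_table_from_dataframe
from .scoring import (
    QC_BAND,
    ExperimentScore,
    GenotypeSummary,
    aggregate_all,
    control_dumping_indices,
    score_screen,
    scores_to_dataframe,
)


class DumpingScreenModel:
    """Pharmaco-genetic interaction screen scored by the dumping index.

    Parameters
    ----------
    table : ScreenTable
        Validated well records.
    qc_band : (low, high)
        Inclusive quality band on the per-experiment control dumping index.
    sigma : float, optional
        Supplied classification SD (e.g. a published aggregate control SD to
        reproduce fixed bands on new data).  When None, sigma is computed
        from this screen's own pooled QC-passing controls.
    """

    def __init__(
        self,
        table: ScreenTable,
        qc_band: tuple[float, float] = QC_BAND,
        sigma: float | None = None,
    ):
        low, high = qc_band
        if not low < high:
            raise ValueError(f"QC band must satisfy low < high, got {qc_band}")
        if sigma is not None and sigma <= 0:
            raise ValueError(f"supplied sigma must be > 0, got {sigma}")
        self.table = table
        self.qc_band = qc_band
        self.sigma = sigma

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        control_genotype: str = "yw",
        dialect: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "DumpingScreenModel":
        return cls(
            screen_table_from_dataframe(df, control_genotype=control_genotype, dialect=dialect),
            **kwargs,
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        control_genotype: str = "yw",
        dialect: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "DumpingScreenModel":
        return cls(
            read_screen_table(path, control_genotype=control_genotype, dialect=dialect), **kwargs
        )

    def fit(self) -> "ScreenResults":
        scores = score_screen(self.table, self.qc_band)
        control = self.table.control_genotype
        summaries = aggregate_all(scores)
        control_dis = control_dumping_indices(scores, control)
        if self.sigma is not None:
            spec = ThresholdSpec.from_sigma(self.sigma)
            sigma_source = "supplied"
        elif len(control_dis) >= 2:
            spec = thresholds_from_controls(control_dis)
            sigma_source = "computed"
        else:
            # scoring and QC reporting stay available; classification needs
            # either >= 2 passing controls or a supplied sigma
            spec = None
            sigma_source = "unavailable"
        calls = (
            dict(classify_screen(summaries, spec, control_genotype=control))
            if spec is not None
            else {}
        )
        return ScreenResults(
            model=self,
            scores=scores,
            summaries=summaries,
            thresholds=spec,
            sigma_source=sigma_source,
            calls=calls,
            control_dis=control_dis,
        )


@dataclass
class ScreenResults:
    """Estimates, uncertainties and calls from a fitted screen."""

    model: DumpingScreenModel
    scores: list[ExperimentScore]
    summaries: list[GenotypeSummary]
    thresholds: ThresholdSpec | None
    sigma_source: str
    calls: dict[str, InteractorClass]
    control_dis: list[float]

    @property
    def control_genotype(self) -> str:
        return self.model.table.control_genotype

    def scores_frame(self) -> pd.DataFrame:
        return scores_to_dataframe(self.scores)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "genotype": s.genotype,
                    "n": s.n,
                    "mean_dumping_index": s.mean_di,
                    "sd_dumping_index": s.sd_di,
                    "mean_normalized_index": s.mean_norm,
                    "sd_normalized_index": s.sd_norm,
                    "class": str(self.calls[s.genotype]) if s.genotype in self.calls else "",
                    "provisional": s.provisional,
                }
            )
        return pd.DataFrame(rows)

    def chart_frame(self) -> pd.DataFrame:
        """Machine-readable twin of the classification chart: one row per
        genotype with its mean normalized index, SD and the threshold lines."""
        if self.thresholds is None:
            raise ValueError(
                "classification unavailable: need >= 2 QC-passing controls or a supplied sigma"
            )
        df = self.summary_frame()[
            ["genotype", "n", "mean_normalized_index", "sd_normalized_index", "class"]
        ].copy()
        df["weak_bound"] = self.thresholds.weak_bound
        df["strong_bound"] = self.thresholds.strong_bound
        return df

    def classification_report(self) -> dict:
        if self.thresholds is None:
            raise ValueError(
                "classification unavailable: need >= 2 QC-passing controls or a supplied sigma"
            )
        experimental = [s for s in self.summaries if s.genotype != self.control_genotype]
        return classification_report(
            experimental,
            self.thresholds,
            control_genotype=self.control_genotype,
            sigma_source=self.sigma_source,
        )

    def _group_stats(self) -> tuple[GroupStats, list[GroupStats]]:
        control_vals = self.control_dis
        groups = []
        for s in self.summaries:
            if s.genotype == self.control_genotype or s.n < 2 or s.sd_di is None:
                continue
            groups.append(GroupStats(label=s.genotype, n=s.n, mean=s.mean_di, sd=s.sd_di))
        ctrl = GroupStats.from_sample(control_vals, label=self.control_genotype)
        return ctrl, groups

    def anova(self) -> TestResult:
        """Ordinary one-way ANOVA over per-experiment dumping indices
        (pooled control + every genotype with n >= 2)."""
        ctrl, groups = self._group_stats()
        return one_way_anova([ctrl] + groups)

    def dunnett(self) -> list[TestResult]:
        """Dunnett many-to-one comparisons of every genotype (n >= 2) against
        the pooled wild-type control dumping indices; one family per call."""
        ctrl, groups = self._group_stats()
        if not groups:
            raise ValueError("no genotype with n >= 2 to compare")
        return dunnett_many_to_one(ctrl, groups, labels=[g.label for g in groups])

    def qc_report(self) -> pd.DataFrame:
        """Per-experiment control dumping index and its QC outcome."""
        rows = [
            {
                "experiment_id": s.experiment_id,
                "control_dumping_index": s.dumping_index,
                "qc_pass": s.qc_pass,
            }
            for s in self.scores
            if s.genotype == self.control_genotype
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a model-results printout."""
        buf = _io.StringIO()
        spec = self.thresholds
        n_exp = len({s.experiment_id for s in self.scores})
        n_fail = len({s.experiment_id for s in self.scores if not s.qc_pass})
        buf.write("Dumping-index screen results\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"control genotype:      {self.control_genotype}\n")
        buf.write(f"experiments scored:    {n_exp} ({n_fail} failed QC {self.model.qc_band})\n")
        if spec is not None:
            buf.write(
                f"sigma ({self.sigma_source}):      {spec.sigma:.4f}  "
                f"bands: +/-{spec.weak_bound:.4f} (weak), +/-{spec.strong_bound:.4f} (strong)\n"
            )
        else:
            buf.write("sigma:                 unavailable (<2 QC-passing controls)\n")
        buf.write("-" * 64 + "\n")
        df = self.summary_frame()
        with pd.option_context("display.float_format", "{:0.4f}".format):
            buf.write(df.to_string(index=False))
        buf.write("\n")
        return buf.getvalue()
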