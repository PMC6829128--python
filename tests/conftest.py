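import pandas as pd
import pytest


def _row(exp, genotype, treatment, mM, s10b, s11, s12, s13_14):
    return {
        "experiment_id": exp,
        "genotype": genotype,
        "treatment": treatment,
        "aspirin_mM": mM,
        "n_s10b": s10b,
        "n_s11": s11,
        "n_s12": s12,
        "n_s13_14": s13_14,
    }


@pytest.fixture
def worked_example_df() -> pd.DataFrame:
    """One complete experiment with exact worked-example arithmetic.

    Control: vehicle 23/25 dumped (0.92), aspirin 23/50 (0.46) -> index 0.5.
    Mutant:  vehicle 18/20 dumped (0.90), aspirin 9/50 (0.18) -> index 0.2,
    normalized -0.3; control index 0.5 passes QC.
    """
    return pd.DataFrame(
        [
            _row("e1", "yw", "vehicle", 0.0, 2, 0, 5, 18),
            _row("e1", "yw", "aspirin", 1.5, 14, 13, 11, 12),
            _row("e1", "mut", "vehicle", 0.0, 2, 0, 8, 10),
            _row("e1", "mut", "aspirin", 1.5, 21, 20, 4, 5),
        ]
    )


@pytest.fixture
def worked_example_csv(tmp_path, worked_example_df):
    path = tmp_path / "screen.csv"
    worked_example_df.to_csv(path, index=False)
    return path


@pytest.fixture
def qc_failing_df(worked_example_df) -> pd.DataFrame:
    """Same experiment but the control aspirin well dumps only 15/50 (0.30):
    control index 0.326 < 0.4, so the whole experiment fails QC."""
    df = worked_example_df.copy()
    mask = (df.genotype == "yw") & (df.treatment == "aspirin")
    df.loc[mask, ["n_s10b", "n_s11", "n_s12", "n_s13_14"]] = [18, 17, 8, 7]
    return df
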