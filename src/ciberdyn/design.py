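"""The 8-sample screen design: pre/post guide induction, then a dose-by-time
grid of stress treatment.

The default design mirrors a two-dose sulfometuron methyl (SM) timecourse:
one pre-induction sample, one sample after CRISPRi guide induction, then the
induced culture split and treated with low (0.56 uM) or high (14 uM) SM and
sampled at 0.25, 1 and 4 hours — eight samples, of which seven are
post-induction ISR measurements.

``elapsed_h`` is hours of growth since guide induction; fitness effects act
over this window.  The default induction window of 8 h corresponds to the
roughly four population doublings a culture traverses between induction and
harvest at the default 2 h doubling time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .library import ParameterError

LOW_DOSE_UM = 0.56
HIGH_DOSE_UM = 14.0
TREATMENT_TIMEPOINTS_H = (0.25, 1.0, 4.0)

PRE_SAMPLE = "pre"
POST_SAMPLE = "post"

SAMPLE_SHEET_COLUMNS = ["sample_id", "phase", "dose", "time_h", "elapsed_h"]


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample in the screen design."""

    sample_id: str
    phase: str  # pre_induction | post_induction | treated
    dose: float  # uM SM; 0 unless treated
    time_h: float | None  # hours since SM addition; None unless treated
    elapsed_h: float  # hours since guide induction

    def __post_init__(self):
        if self.phase not in ("pre_induction", "post_induction", "treated"):
            raise ParameterError(f"unknown phase {self.phase!r}")
        if self.dose > 0 and self.phase != "treated":
            raise ParameterError("dose > 0 requires phase 'treated'")
        if self.phase == "treated" and self.time_h is None:
            raise ParameterError("treated samples need a treatment time")


def _fmt_time(t: float) -> str:
    return f"{t:g}h".replace(".", "p")


def default_design(
    t_induction_h: float = 8.0,
    low_dose: float = LOW_DOSE_UM,
    high_dose: float = HIGH_DOSE_UM,
    timepoints_h: tuple = TREATMENT_TIMEPOINTS_H,
) -> list[SampleMeta]:
    """The standard 8-sample dose-by-time design."""
    samples = [
        SampleMeta(PRE_SAMPLE, "pre_induction", 0.0, None, 0.0),
        SampleMeta(POST_SAMPLE, "post_induction", 0.0, None, t_induction_h),
    ]
    for label, dose in (("low", low_dose), ("high", high_dose)):
        for t in timepoints_h:
            samples.append(
                SampleMeta(f"{label}_{_fmt_time(t)}", "treated", dose, t, t_induction_h + t)
            )
    return samples


def post_induction_samples(design: list[SampleMeta]) -> list[SampleMeta]:
    """The seven ISR measurements taken after guide induction."""
    return [s for s in design if s.phase != "pre_induction"]


def design_to_frame(design: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "phase": [s.phase for s in design],
            "dose": [s.dose for s in design],
            "time_h": [s.time_h for s in design],
            "elapsed_h": [s.elapsed_h for s in design],
        }
    )


def design_from_frame(df: pd.DataFrame) -> list[SampleMeta]:
    out = []
    for r in df.itertuples():
        t = None if pd.isna(r.time_h) else float(r.time_h)
        out.append(SampleMeta(str(r.sample_id), str(r.phase), float(r.dose), t, float(r.elapsed_h)))
    return out


def write_sample_sheet(design: list[SampleMeta], path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[SampleMeta]:
    return design_from_frame(pd.read_csv(path, sep="\t"))
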