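"""End-to-end orchestration: simulate -> score -> quantify -> proximity ->
consensus -> neoepitopes -> ELISpot -> report."""

from __future__ import annotations

from pathlib import Path

from .cohort_report import CohortReport, ReportConfig, build_report
from .synthetic_cohort import CohortDataset, CohortParams, generate_patient_cohort


def run_all(
    params: CohortParams | None = None,
    cohort: CohortDataset | None = None,
    out=None,
) -> tuple[CohortDataset, CohortReport]:
    """Generate (or take) a cohort and run every analysis stage over it.

    Returns the cohort and the assembled report; with ``out`` set, writes
    the cohort directory and report tables there.
    """
    if cohort is None:
        params = params if params is not None else CohortParams()
        cohort = generate_patient_cohort(params)
    config = ReportConfig(
        max_selected_per_patient=cohort.params.max_synthesized_per_patient
    )
    report = build_report(cohort, config)
    if out is not None:
        out = Path(out)
        cohort.write(out / "cohort")
        report.write(out / "report")
    return cohort, report
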