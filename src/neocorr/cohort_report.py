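"""Cohort-level association tests, printed-rate computation, and reports.

Association tests mirror standard small-cohort practice: two-tailed
Mann-Whitney U for responder-vs-non-responder comparisons, Wilcoxon
signed-rank for paired pre/post data, a one-sample t test of log2 fold
changes against zero, and ordinary least squares with an F test of the
slope for paired continuous correlates. No multiple-testing correction is
applied; the report records the number of tests performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away
from .errors import DegenerateInputError, ParameterError
from . import elispot_response as er
from . import mif_quantification as mif
from . import neoepitope_pipeline as neo
from . import response_scoring as rs
from . import spatial_proximity as sp
from . import variant_consensus as vc

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_cohort import CohortDataset

SIGNIFICANCE = 0.05
EXACT_MW_MAX_N = 8


def rate_percent(numerator: int, denominator: int) -> int:
    """Printed-style integer percentage, rounded half away from zero."""
    if denominator <= 0:
        raise DegenerateInputError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ParameterError("numerator must be between 0 and denominator")
    return round_half_away(100.0 * numerator / denominator)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n_pr: int
    n_non: int
    method: str


def compare_by_response(values: Sequence[float], pr_flags: Sequence[bool]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U of a correlate between PR and non-PR patients.

    Uses the exact null distribution when both groups have at most 8
    untied observations, the tie-corrected normal approximation otherwise.
    An empty group yields the NaN sentinel rather than an error. NaN values
    (missing modality) are dropped pairwise with their labels.
    """
    v = np.asarray(values, dtype=float)
    f = np.asarray(pr_flags, dtype=bool)
    if v.shape != f.shape:
        raise ParameterError("values and pr_flags must align")
    keep = ~np.isnan(v)
    v, f = v[keep], f[keep]
    g1, g0 = v[f], v[~f]
    if len(g1) == 0 or len(g0) == 0:
        return MannWhitneyResult(float("nan"), float("nan"), len(g1), len(g0), "undefined")
    ties = len(np.unique(v)) < len(v)
    if max(len(g1), len(g0)) <= EXACT_MW_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), len(g1), len(g0), method)


def wilcoxon_paired(pre: Sequence[float], post: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired pre/post data.

    Zero differences are dropped; if none remain the undefined-result
    sentinel (NaN) is returned.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ParameterError("paired vectors must have equal length")
    diffs = post - pre
    if np.all(diffs == 0) or len(diffs[diffs != 0]) < 2:
        return float("nan")
    res = stats.wilcoxon(pre, post, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def one_sample_t(values: Sequence[float], popmean: float = 0.0) -> float:
    """Two-sided one-sample t test p against ``popmean``.

    A zero-variance sample is degenerate for the t statistic; by convention
    it returns p=1 when the common value equals the null mean (no evidence
    of a shift) and p=0 otherwise (every observation is shifted).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return float("nan")
    if np.ptp(v) == 0:
        return 1.0 if v[0] == popmean else 0.0
    return float(stats.ttest_1samp(v, popmean).pvalue)


@dataclass(frozen=True)
class PairedTests:
    wilcoxon_p: float
    t_p: float


def paired_and_one_sample_tests(
    pre: Sequence[float],
    post: Sequence[float],
    log2fc: Sequence[float] | None = None,
) -> PairedTests:
    """Wilcoxon signed-rank on the pairs plus one-sample t of log2 FC vs 0."""
    if log2fc is None:
        log2fc = [mif.log2_fc(a, b) for a, b in zip(pre, post)]
    return PairedTests(wilcoxon_paired(pre, post), one_sample_t(log2fc, 0.0))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float  # goodness-of-fit F test of slope != 0


def regression_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with an F test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError("x and y must have equal length")
    if len(x) < 3:
        raise ParameterError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# full-cohort report assembly


@dataclass(frozen=True)
class ReportConfig:
    """Analysis knobs for build_report; defaults match the library defaults."""

    speculative_ln_cr: bool = False
    proximity: sp.ProximityConfig = field(default_factory=sp.ProximityConfig)
    max_selected_per_patient: int = neo.DEFAULT_MAX_PER_PATIENT


@dataclass
class CohortReport:
    patient_table: pd.DataFrame  # waterfall-ordered, one row per patient
    association_table: pd.DataFrame
    rates: dict
    n_tests: int

    @property
    def responders(self) -> set:
        t = self.patient_table
        return set(t.loc[t["pr_flag"].astype(bool), "patient_id"])

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, float) and np.isnan(obj):
                return None
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        payload = {
            "rates": {k: _clean(v) for k, v in self.rates.items()},
            "n_tests": self.n_tests,
            "patients": json.loads(self.patient_table.to_json(orient="records")),
            "associations": json.loads(self.association_table.to_json(orient="records")),
        }
        return json.dumps(payload, indent=2)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patient_table.to_csv(outdir / "patient_summary.tsv", sep="\t", index=False)
        self.association_table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _analyze_mif(patient, config: ReportConfig) -> dict:
    out = {}
    dens = {}
    for tp, cells_raw in (("pre", patient.cells_pre), ("post", patient.cells_post)):
        cells = mif.assign_phenotypes(cells_raw)
        areas = patient.mif_areas[tp]
        whole = areas["tumor"] + areas["stroma"]
        d = {}
        for ph in ("CD8 T cell", "CD4 T cell", "Treg", "PMN", "Macrophage"):
            for comp, area in (("tumor", areas["tumor"]), ("stroma", areas["stroma"]),
                               ("whole", whole)):
                d[(ph, comp)] = (
                    mif.cell_density(cells, ph, comp, area).density if area > 0 else 0.0
                )
        dens[tp] = d
        tumor_cells = cells[cells["phenotype"] == "Tumor cell"]
        out[f"{tp}_tumor_ki67_hscore"] = mif.h_score_from_cells(tumor_cells, "ki67")
        stroma = cells[cells["compartment"] == "stroma"]
        out[f"{tp}_stromal_immune_fraction"] = mif.stromal_immune_fraction(stroma)
        out[f"{tp}_tumor_cd8_density"] = d[("CD8 T cell", "tumor")]
        out[f"{tp}_stromal_treg_density"] = d[("Treg", "stroma")]
        out[f"{tp}_stromal_myeloid_density"] = d[("PMN", "stroma")] + d[("Macrophage", "stroma")]
        for comp in ("tumor", "stroma", "whole"):
            out[f"{tp}_cd8_treg_ratio_{comp}"] = mif.cd8_treg_ratio(
                d[("CD8 T cell", comp)], d[("Treg", comp)]
            )
        # proximity per T cell class
        res = sp.proximity_by_class(cells, config.proximity)
        out[f"_proximity_{tp}"] = res
    out["log2fc_tumor_cd8_density"] = mif.log2_fc(
        out["pre_tumor_cd8_density"], out["post_tumor_cd8_density"]
    )
    out["log2fc_tumor_ki67_hscore"] = mif.log2_fc(
        out["pre_tumor_ki67_hscore"], out["post_tumor_ki67_hscore"]
    )
    for comp in ("tumor", "stroma", "whole"):
        out[f"log2fc_cd8_treg_ratio_{comp}"] = mif.log2_fc(
            out[f"pre_cd8_treg_ratio_{comp}"], out[f"post_cd8_treg_ratio_{comp}"]
        )
    shifts = []
    for label in ("Ki67+CD8", "Ki67+CD4"):
        s = sp.proximity_shift(out["_proximity_pre"][label], out["_proximity_post"][label])
        out[f"proximity_shift_{label}"] = s
        if not np.isnan(s):
            shifts.append(s)
    out["proximity_shift_ki67"] = float(np.mean(shifts)) if shifts else float("nan")
    del out["_proximity_pre"], out["_proximity_post"]
    return out


def _analyze_variants(patient, predictor, config: ReportConfig) -> dict:
    snvs = vc.consensus_snvs(list(patient.snv_callsets.values()))
    indels = vc.consensus_indels(list(patient.indel_callsets.values()))
    consensus = vc.attach_annotations(
        snvs + indels, patient.annotations, patient.tpm, patient.pretreatment_keys
    )
    cands = neo.candidates_from_variants(
        consensus, patient.proteins, patient.hla_alleles, predictor
    )
    ranked = neo.rank_candidates(cands)
    selected = neo.select_candidates(ranked, max_per_patient=config.max_selected_per_patient)
    return {
        "n_mutations": len(consensus),
        "n_predicted_neoepitopes_ic50_500": neo.count_predicted(ranked),
        "n_selected_neoepitopes": len(selected),
        "_selected_peptides": [c.peptide for c in selected],
    }


def build_report(cohort: "CohortDataset", config: ReportConfig | None = None) -> CohortReport:
    """Run every analysis stage over a cohort and assemble the report.

    Returns the per-patient summary table (ordered by decreasing primary
    pTR, the waterfall order), the responder-vs-correlate association
    table, and the cohort rate summary. Missing modalities (e.g., patients
    without TIL cultures) are reported as missing, not dropped rows.
    """
    config = config or ReportConfig()
    predictor = cohort.predictor

    elispot_by_patient = {}
    if cohort.elispot_plates is not None and len(cohort.elispot_plates):
        flags = er.classify_plate(cohort.elispot_plates)
        for summ in er.patient_aggregates(flags):
            elispot_by_patient[summ.patient_id] = summ

    rows = []
    for patient in cohort.patients:
        row = {"patient_id": patient.patient_id}
        primary_ptr = rs.compute_ptr([s for s in patient.slide_areas if s.site == "primary"])
        call = rs.classify_response(primary_ptr)
        row["primary_ptr"] = primary_ptr
        row["primary_class"] = call.response_class.value
        row["pr_flag"] = call.pr_flag

        ln_slides = [s for s in patient.slide_areas if s.site == "LN"]
        possible_cr = patient.ln_status == "suspicious_n0"
        ln_ptr = rs.compute_ptr(ln_slides) if ln_slides else None
        row["ln_ptr"] = ln_ptr
        row["possible_ln_cr"] = possible_cr
        if ln_ptr is not None or possible_cr:
            row["discordant"] = rs.classify_discordance(primary_ptr, ln_ptr, possible_cr)
        else:
            row["discordant"] = None
        ln_pr_confirmed = ln_ptr is not None and ln_ptr >= rs.PR_THRESHOLD
        row["any_site_ppr"] = call.pr_flag or ln_pr_confirmed
        row["any_site_ppr_speculative"] = row["any_site_ppr"] or possible_cr

        pre_p = [m for m in patient.lesions if m.site == "primary" and m.timepoint == "pre"]
        post_p = [m for m in patient.lesions if m.site == "primary" and m.timepoint == "post"]
        row["primary_volume_change_pct"] = (
            rs.volume_change(pre_p, post_p) if pre_p and post_p else float("nan")
        )

        row.update(_analyze_mif(patient, config))
        row.update(_analyze_variants(patient, predictor, config))
        row.pop("_selected_peptides")

        summ = elispot_by_patient.get(patient.patient_id)
        row["elispot_assayed"] = summ is not None
        row["n_positive_neoepitopes"] = summ.n_positive_neoepitopes if summ else float("nan")
        row["cumulative_spot_count"] = summ.cumulative_spot_count if summ else float("nan")
        row["cef_positive"] = summ.cef_positive if summ else None
        row["increased_neoepitope_immunity"] = (
            (summ.n_increased > 0) if summ else None
        )
        row["recurrence_free_1yr"] = not patient.recurrence_within_1yr
        rows.append(row)

    table = pd.DataFrame(rows).sort_values(
        ["primary_ptr", "patient_id"], ascending=[False, True], ignore_index=True
    )

    pr = table["pr_flag"].astype(bool).to_numpy()
    metrics = [
        ("log2fc_tumor_cd8_density", "log2 FC tumor CD8 density"),
        ("log2fc_cd8_treg_ratio_tumor", "log2 FC tumor CD8/Treg ratio"),
        ("log2fc_cd8_treg_ratio_stroma", "log2 FC stromal CD8/Treg ratio"),
        ("pre_stromal_myeloid_density", "pretreatment stromal myeloid density"),
        ("log2fc_tumor_ki67_hscore", "log2 FC tumor Ki67 H-score"),
        ("proximity_shift_ki67", "log2 FC Ki67+ T cell-Treg mean distance"),
        ("n_positive_neoepitopes", "positive neoepitope responses"),
        ("cumulative_spot_count", "cumulative neoepitope IFN-g spots"),
        ("n_mutations", "mutational burden"),
        ("n_predicted_neoepitopes_ic50_500", "predicted neoepitopes (IC50<500)"),
    ]
    assoc_rows = []
    for col, label in metrics:
        res = compare_by_response(table[col].to_numpy(dtype=float), pr)
        assoc_rows.append({
            "metric": col, "label": label, "u": res.u, "p": res.p,
            "n_pr": res.n_pr, "n_non": res.n_non, "method": res.method,
            "significant": bool(res.p < SIGNIFICANCE) if not np.isnan(res.p) else None,
        })
    associations = pd.DataFrame(assoc_rows)

    n = len(table)
    assayed = table[table["elispot_assayed"]]
    n_assayed = len(assayed)
    rates = {
        "n_patients": n,
        "primary_pr_rate_percent": rate_percent(int(pr.sum()), n),
        "rfs_1yr_percent": rate_percent(int(table["recurrence_free_1yr"].sum()), n),
        "any_site_ppr_percent": rate_percent(int(table["any_site_ppr"].sum()), n),
        "any_site_ppr_speculative_percent": rate_percent(
            int(table["any_site_ppr_speculative"].sum()), n
        ),
        "discordant_percent": (
            rate_percent(
                int(sum(1 for v in table["discordant"] if v is not None and bool(v))),
                int(sum(1 for v in table["discordant"] if v is not None)),
            )
            if any(v is not None for v in table["discordant"])
            else None
        ),
        "cef_positive_percent": (
            rate_percent(int(assayed["cef_positive"].astype(bool).sum()), n_assayed)
            if n_assayed
            else None
        ),
        "increased_immunity_percent": (
            rate_percent(
                int(assayed["increased_neoepitope_immunity"].astype(bool).sum()), n_assayed
            )
            if n_assayed
            else None
        ),
    }
    return CohortReport(table, associations, rates, n_tests=len(assoc_rows))
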