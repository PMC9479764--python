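"""ELISpot response calling from duplicate IFN-gamma spot counts.

Each coculture condition (one neoepitope peptide, the CEF viral recall
pool, a positive control, or a no-peptide background well) is run in
technical duplicate at both timepoints; the mean of the duplicates is the
reported spot count. Calling rules: a response is *detected* when the mean
count is above 0, *positive* when the post-treatment mean is 5 or higher,
and *increased* when the post-minus-pre difference in means exceeds 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

POSITIVE_THRESHOLD = 5.0
INCREASE_THRESHOLD = 5.0

#: reserved (non-neoepitope) condition names in plate tables
CEF_CONDITION = "CEF"
CONTROL_CONDITION = "E7"
BACKGROUND_CONDITION = "no_peptide"
RESERVED_CONDITIONS = (CEF_CONDITION, CONTROL_CONDITION, BACKGROUND_CONDITION)


def condition_category(condition: str) -> str:
    if condition == CEF_CONDITION:
        return "cef"
    if condition == CONTROL_CONDITION:
        return "control"
    if condition == BACKGROUND_CONDITION:
        return "background"
    return "neoepitope"


@dataclass(frozen=True)
class ElispotCondition:
    patient_id: str
    condition: str
    timepoint: str  # "pre" or "post"
    replicate_counts: tuple

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.replicate_counts):
            raise ParameterError("spot counts must be nonnegative")
        if not self.replicate_counts:
            raise ParameterError("at least one replicate required")

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.replicate_counts))


@dataclass(frozen=True)
class ResponseFlags:
    """Per-condition calls; None marks a missing timepoint."""

    detected_pre: bool | None
    detected_post: bool | None
    positive: bool | None
    increased: bool | None


def classify_condition(
    pre: ElispotCondition | None, post: ElispotCondition | None
) -> ResponseFlags:
    """Detected/positive/increased flags for one condition.

    Means are computed before thresholding. A missing timepoint yields
    partial flags (None for anything needing that timepoint).
    """
    if pre is not None and post is not None:
        if (pre.patient_id, pre.condition) != (post.patient_id, post.condition):
            raise ParameterError("pre/post conditions do not match")
    detected_pre = None if pre is None else pre.mean_count > 0
    detected_post = None if post is None else post.mean_count > 0
    positive = None if post is None else post.mean_count >= POSITIVE_THRESHOLD
    increased = (
        None
        if pre is None or post is None
        else (post.mean_count - pre.mean_count) > INCREASE_THRESHOLD
    )
    return ResponseFlags(detected_pre, detected_post, positive, increased)


def classify_plate(plate: pd.DataFrame, background_subtract: bool = False) -> pd.DataFrame:
    """Flags for every condition of a plate table.

    ``plate`` columns: patient_id, condition, timepoint, rep1, rep2.
    With ``background_subtract`` the matching no-peptide mean is removed
    from every condition mean (floored at 0) before the rules apply.
    """
    df = plate.copy()
    df["mean_count"] = (df["rep1"] + df["rep2"]) / 2.0
    if (df["mean_count"] < 0).any():
        raise ParameterError("spot counts must be nonnegative")
    if background_subtract:
        bg = (
            df[df["condition"] == BACKGROUND_CONDITION]
            .set_index(["patient_id", "timepoint"])["mean_count"]
        )
        def _sub(row):
            b = bg.get((row["patient_id"], row["timepoint"]), 0.0)
            return max(row["mean_count"] - b, 0.0)
        df["mean_count"] = df.apply(_sub, axis=1)

    wide = df.pivot_table(
        index=["patient_id", "condition"], columns="timepoint",
        values="mean_count", aggfunc="mean",
    )
    rows = []
    for (pid, cond), r in wide.iterrows():
        pre = r.get("pre", np.nan)
        post = r.get("post", np.nan)
        has_pre, has_post = not np.isnan(pre), not np.isnan(post)
        rows.append({
            "patient_id": pid,
            "condition": cond,
            "category": condition_category(cond),
            "pre_mean": pre,
            "post_mean": post,
            "detected_pre": bool(pre > 0) if has_pre else None,
            "detected_post": bool(post > 0) if has_post else None,
            "positive": bool(post >= POSITIVE_THRESHOLD) if has_post else None,
            "increased": bool((post - pre) > INCREASE_THRESHOLD) if has_pre and has_post else None,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PatientElispotSummary:
    patient_id: str
    n_tested: int
    n_positive_neoepitopes: int
    n_detected_pre: int
    n_increased: int
    cumulative_spot_count: float
    cef_positive: bool


def patient_aggregates(flags: pd.DataFrame) -> list[PatientElispotSummary]:
    """Per-patient neoepitope-response aggregates from classify_plate output.

    ``n_positive_neoepitopes`` counts positive neoepitope conditions;
    ``cumulative_spot_count`` sums post-treatment means over all neoepitope
    conditions. CEF is handled separately and never counted as a
    neoepitope.
    """
    def _b(series: pd.Series) -> np.ndarray:
        # robust truthiness: None and NaN (missing timepoint) count as False
        return np.array([v is not None and v == v and bool(v) for v in series])

    out = []
    for pid, g in flags.groupby("patient_id", sort=True):
        neo = g[g["category"] == "neoepitope"]
        cef = g[g["category"] == "cef"]
        pos = _b(neo["positive"])
        out.append(
            PatientElispotSummary(
                patient_id=pid,
                n_tested=int(len(neo)),
                n_positive_neoepitopes=int(pos.sum()),
                n_detected_pre=int((pos & _b(neo["detected_pre"])).sum()),
                n_increased=int((pos & _b(neo["increased"])).sum()),
                cumulative_spot_count=float(neo["post_mean"].fillna(0).sum()),
                cef_positive=bool(_b(cef["positive"]).any()),
            )
        )
    return out
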