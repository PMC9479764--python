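"""Pathologic and radiographic tumor response scoring.

Pathologic tumor response (pTR) is expressed as percent *regression* of the
tumor bed: 100 minus the percentage of the bed surface still occupied by
viable tumor, pooled over all slides of a specimen (pooling the areas before
dividing is the surface-area-weighted mean). Response classes follow the
standard immune-related pathologic response definitions:

* pCR  — no residual viable tumor (pTR = 100)
* MPR  — major response, <=10% residual viable tumor (90 <= pTR < 100)
* pPR  — partial response, 11-50% residual viable tumor (50 <= pTR < 90)
* NR   — no response (pTR < 50)

and a PR for correlative purposes is pTR >= 50. Radiographic lesion volume
is the product of the longest perpendicular bidimensional measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from ._util import round_half_away
from .errors import DegenerateInputError, ParameterError

PR_THRESHOLD = 50


class ResponseClass(str, Enum):
    pCR = "pCR"
    MPR = "MPR"
    pPR = "pPR"
    NR = "NR"


@dataclass(frozen=True)
class SlideAreaRecord:
    """Viable-tumor and tumor-bed surface areas for one H&E slide."""

    patient_id: str
    site: str  # "primary" or "LN"
    block_id: str
    viable_area_mm2: float
    bed_area_mm2: float

    def __post_init__(self) -> None:
        if self.site not in ("primary", "LN"):
            raise ParameterError(f"site must be 'primary' or 'LN', got {self.site!r}")
        if not self.viable_area_mm2 >= 0:
            raise ParameterError("viable_area_mm2 must be >= 0")
        if not self.bed_area_mm2 > 0:
            raise ParameterError("bed_area_mm2 must be > 0")
        if self.viable_area_mm2 > self.bed_area_mm2:
            raise ParameterError("viable area cannot exceed bed area")


@dataclass(frozen=True)
class ResponseCall:
    ptr_percent: int
    response_class: ResponseClass
    pr_flag: bool
    possible_ln_cr: bool = False


@dataclass
class LesionMeasurement:
    """One bidimensional lesion measurement (mm); length >= width on ingest."""

    patient_id: str
    site: str
    timepoint: str  # "pre" or "post"
    length_mm: float
    width_mm: float
    suspicious_flag: bool = False

    def __post_init__(self) -> None:
        if not (self.length_mm > 0 and self.width_mm > 0):
            raise ParameterError("lesion dimensions must be positive")
        if self.width_mm > self.length_mm:
            self.length_mm, self.width_mm = self.width_mm, self.length_mm

    @property
    def area_mm2(self) -> float:
        return self.length_mm * self.width_mm


def compute_ptr(slides: Sequence[SlideAreaRecord]) -> int:
    """Pooled pTR (% regression) over the slides of one patient/site.

    Pools viable and bed areas before dividing, which is the bed-area-weighted
    mean of per-slide viable percentages, then rounds half away from zero to
    the nearest integer percent.
    """
    slides = list(slides)
    if not slides:
        raise ParameterError("compute_ptr requires at least one slide")
    keys = {(s.patient_id, s.site) for s in slides}
    if len(keys) > 1:
        raise ParameterError(f"slides span multiple patient/site pairs: {sorted(keys)}")
    total_bed = sum(s.bed_area_mm2 for s in slides)
    total_viable = sum(s.viable_area_mm2 for s in slides)
    if total_bed <= 0:
        raise DegenerateInputError("total tumor bed area is zero")
    return round_half_away(100.0 * (1.0 - total_viable / total_bed))


def classify_response(ptr: int, possible_ln_cr: bool = False) -> ResponseCall:
    """Map an integer pTR percent onto the response-class partition."""
    ptr = int(ptr)
    if not 0 <= ptr <= 100:
        raise ParameterError(f"pTR must be in [0, 100], got {ptr}")
    if ptr == 100:
        cls = ResponseClass.pCR
    elif ptr >= 90:
        cls = ResponseClass.MPR
    elif ptr >= PR_THRESHOLD:
        cls = ResponseClass.pPR
    else:
        cls = ResponseClass.NR
    return ResponseCall(ptr, cls, pr_flag=ptr >= PR_THRESHOLD, possible_ln_cr=possible_ln_cr)


def classify_discordance(
    primary_ptr: int, ln_ptr: int | None = None, ln_possible_cr: bool = False
) -> bool:
    """True when primary and nodal responses differ by more than 20 points.

    A possible nodal complete response (suspicious node, pathologically
    negative) counts as a 100% nodal response.
    """
    if ln_possible_cr:
        ln_ptr = 100
    if ln_ptr is None:
        raise ParameterError("LN response unavailable; cannot assess discordance")
    return abs(int(primary_ptr) - int(ln_ptr)) > 20


def _total_volume(lesions: LesionMeasurement | Iterable[LesionMeasurement]) -> float:
    if isinstance(lesions, LesionMeasurement):
        lesions = [lesions]
    return sum(m.area_mm2 for m in lesions)


def volume_change(
    pre: LesionMeasurement | Iterable[LesionMeasurement],
    post: LesionMeasurement | Iterable[LesionMeasurement],
) -> float:
    """Percent change in summed bidimensional lesion volume, post vs pre."""
    pre_vol = _total_volume(pre)
    post_vol = _total_volume(post)
    if pre_vol <= 0:
        raise DegenerateInputError("pretreatment lesion volume is zero")
    return 100.0 * (post_vol - pre_vol) / pre_vol
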