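"""Synthetic patient cohorts with the statistical structure the analyses assume.

The generator emulates, per patient and timepoint, every input the pipeline
consumes: segmented MIF cell tables with tumor-nest geometry and a
configurable Treg-exclusion point pattern around proliferating T cells,
pathology slide areas, lesion measurements, a somatic-variant truth set
with noisy per-caller call sets, expression and protein context for
neoepitope enumeration, and ELISpot plates with responder-dependent
post-treatment inflation. Every quantity derives from a single splittable
seed, so any sub-object is reproducible in isolation and the same seed
yields byte-identical cohorts.

Planted responder effects (the structure the cohort-level tests recover):
responders receive pTR >= 50, a post-treatment influx of intratumoral CD8
T cells with stromal Treg loss, collapse of the Treg exclusion radius
around Ki67+ T cells, lower pretreatment stromal myeloid density, and a
higher fraction of immunogenic neoepitopes on the ELISpot plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import unary_union
from shapely import contains_xy

from ._util import as_rng, round_half_away
from .errors import ParameterError
from . import elispot_response as er
from . import neoepitope_pipeline as neo
from .response_scoring import LesionMeasurement, SlideAreaRecord
from .variant_consensus import (
    CallerCallSet,
    ConsensusVariant,
    INDEL_CALLERS,
    SNV_CALLERS,
    VariantAnnotation,
    VariantKey,
)

PHENOTYPES = ("CD8 T cell", "CD4 T cell", "Treg", "PMN", "Macrophage")
_IMMUNE_DIAMETER = (9.0, 1.5)  # mean, sd um
_OTHER_DIAMETER = (18.0, 3.0)
TREG_PLACEMENT_ATTEMPTS = 100

CELL_COLUMNS = (
    "cell_id", "x_um", "y_um", "compartment", "phenotype",
    "cd3", "cd8", "cd4", "foxp3", "ki67", "pdl1", "ck",
    "pmn_marker", "mac_marker", "intensity_bin", "diameter_um", "roundness",
)


def _default_stromal():
    return {"CD8 T cell": 200.0, "CD4 T cell": 150.0, "Treg": 80.0,
            "PMN": 150.0, "Macrophage": 120.0}


def _default_intratumoral():
    return {"CD8 T cell": 60.0, "CD4 T cell": 40.0, "Treg": 30.0,
            "PMN": 40.0, "Macrophage": 50.0}


@dataclass(frozen=True)
class SlidePatternParams:
    """Point-pattern parameters for one synthetic MIF slide.

    Tumor nests are random discs; the compartment of a cell is decided by
    point-in-nest membership. ``treg_exclusion_radius_um`` is the minimum
    allowed distance between a Treg and any Ki67+ FoxP3- T cell: 0 gives
    complete spatial randomness between Tregs and proliferating T cells.
    """

    field_width_um: float = 1500.0
    field_height_um: float = 1500.0
    tumor_nest_count: int = 4
    nest_radius_mean_um: float = 280.0
    nest_radius_sd_um: float = 60.0
    tumor_cell_density: float = 1500.0  # cells/mm^2 of tumor parenchyma
    stromal_densities: dict = field(default_factory=_default_stromal)
    intratumoral_densities: dict = field(default_factory=_default_intratumoral)
    stromal_other_density: float = 200.0  # CK- non-immune stromal cells
    ki67_fraction_tcell: float = 0.25
    ki67_fraction_tumor: float = 0.5
    treg_exclusion_radius_um: float = 40.0
    pdl1_fraction_myeloid: float = 0.5
    pdl1_fraction_tumor: float = 0.3
    intensity_bin_probs: tuple = (0.25, 0.35, 0.25, 0.15)
    cell_diameter_mean_um: float = 14.0
    cell_diameter_sd_um: float = 2.5

    def __post_init__(self) -> None:
        if not (self.field_width_um > 0 and self.field_height_um > 0):
            raise ParameterError("field dimensions must be positive")
        if self.tumor_nest_count < 0:
            raise ParameterError("tumor_nest_count must be >= 0")
        densities = [self.tumor_cell_density, self.stromal_other_density,
                     *self.stromal_densities.values(), *self.intratumoral_densities.values()]
        for d in densities:
            if not (math.isfinite(d) and d >= 0):
                raise ParameterError(f"densities must be finite and >= 0, got {d}")
        for p in (self.ki67_fraction_tcell, self.ki67_fraction_tumor,
                  self.pdl1_fraction_myeloid, self.pdl1_fraction_tumor):
            if not 0 <= p <= 1:
                raise ParameterError("fractions must be in [0, 1]")
        if self.treg_exclusion_radius_um < 0:
            raise ParameterError("treg_exclusion_radius_um must be >= 0")
        if len(self.intensity_bin_probs) != 4 or abs(sum(self.intensity_bin_probs) - 1) > 1e-9:
            raise ParameterError("intensity_bin_probs must be a 4-vector summing to 1")
        if set(self.stromal_densities) != set(PHENOTYPES) or (
            set(self.intratumoral_densities) != set(PHENOTYPES)
        ):
            raise ParameterError(f"density dicts must cover exactly {PHENOTYPES}")


@dataclass(frozen=True)
class SlideSample:
    """A generated slide: cell table plus compartment surface areas."""

    cells: pd.DataFrame
    tumor_area_mm2: float
    stroma_area_mm2: float


def _nest_union(params: SlidePatternParams, rng: np.random.Generator):
    W, H = params.field_width_um, params.field_height_um
    frame = box(0, 0, W, H)
    discs = []
    for _ in range(params.tumor_nest_count):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        r = max(50.0, rng.normal(params.nest_radius_mean_um, params.nest_radius_sd_um))
        discs.append(Point(cx, cy).buffer(r, quad_segs=32))
    if not discs:
        return None, frame
    union = unary_union(discs).intersection(frame)
    return union, frame


def _sample_points(n: int, params, union, inside: bool, rng) -> np.ndarray:
    """Rejection-sample n points uniformly in the tumor (inside) or stromal
    (outside) compartment."""
    if n == 0:
        return np.empty((0, 2))
    W, H = params.field_width_um, params.field_height_um
    pts = np.empty((0, 2))
    guard = 0
    while len(pts) < n:
        m = max(256, 4 * (n - len(pts)))
        cand = rng.uniform((0, 0), (W, H), size=(m, 2))
        if union is None:
            mask = np.zeros(m, dtype=bool) if inside else np.ones(m, dtype=bool)
        else:
            mask = contains_xy(union, cand[:, 0], cand[:, 1])
            if not inside:
                mask = ~mask
        pts = np.vstack([pts, cand[mask]])
        guard += 1
        if guard > 200:  # degenerate geometry (compartment area ~ 0)
            break
    return pts[:n]


def _single_point(params, union, inside: bool, rng) -> np.ndarray | None:
    pt = _sample_points(1, params, union, inside, rng)
    return pt[0] if len(pt) else None


def generate_cell_slide(params: SlidePatternParams, seed) -> SlideSample:
    """Generate one slide's segmented-cell table.

    Cells carry coordinates inside the field, a compartment label (tumor
    parenchyma when inside a nest, else stroma), boolean marker states
    consistent with exactly one phenotype gate, a scaled intensity bin, a
    diameter, a roundness value and a cytokeratin flag. When
    ``treg_exclusion_radius_um`` > 0, Treg positions violating the radius
    around any Ki67+ FoxP3- T cell are resampled (up to 100 attempts, then
    dropped), planting the avoidance pattern the proximity analysis is
    meant to detect.
    """
    rng = as_rng(seed)
    union, _frame = _nest_union(params, rng)
    field_mm2 = params.field_width_um * params.field_height_um / 1e6
    tumor_mm2 = 0.0 if union is None else union.area / 1e6
    stroma_mm2 = field_mm2 - tumor_mm2

    records: list[dict] = []

    def add_cells(xy, compartment, phenotype, markers, ki67_p, pdl1_p, diam_ms, round_ms):
        n = len(xy)
        if n == 0:
            return
        ki67 = rng.random(n) < ki67_p
        pdl1 = rng.random(n) < pdl1_p
        bins = rng.choice(4, size=n, p=np.asarray(params.intensity_bin_probs))
        diam = np.clip(rng.normal(diam_ms[0], diam_ms[1], size=n), 4.0, 40.0)
        roundness = np.clip(rng.normal(round_ms[0], round_ms[1], size=n), 0.0, 1.0)
        for i in range(n):
            rec = {
                "x_um": xy[i, 0], "y_um": xy[i, 1], "compartment": compartment,
                "phenotype": phenotype,
                "cd3": False, "cd8": False, "cd4": False, "foxp3": False,
                "ck": False, "pmn_marker": False, "mac_marker": False,
                "ki67": bool(ki67[i]), "pdl1": bool(pdl1[i]),
                "intensity_bin": int(bins[i]), "diameter_um": float(diam[i]),
                "roundness": float(roundness[i]),
            }
            rec.update(markers)
            records.append(rec)

    MARKERS = {
        "CD8 T cell": {"cd3": True, "cd8": True},
        "CD4 T cell": {"cd3": True, "cd4": True},
        "Treg": {"cd3": True, "cd4": True, "foxp3": True},
        "PMN": {"pmn_marker": True},
        "Macrophage": {"mac_marker": True},
        "Tumor cell": {"ck": True},
        "other": {},
    }

    # tumor cells
    n_tumor = rng.poisson(params.tumor_cell_density * tumor_mm2)
    add_cells(_sample_points(n_tumor, params, union, True, rng), "tumor", "Tumor cell",
              MARKERS["Tumor cell"], params.ki67_fraction_tumor, params.pdl1_fraction_tumor,
              (params.cell_diameter_mean_um, params.cell_diameter_sd_um), (0.7, 0.1))

    # immune cells per compartment; Tregs deferred for the exclusion constraint
    treg_slots: list[tuple[str, np.ndarray]] = []
    for compartment, inside, dens, area in (
        ("stroma", False, params.stromal_densities, stroma_mm2),
        ("tumor", True, params.intratumoral_densities, tumor_mm2),
    ):
        for ph in PHENOTYPES:
            n = rng.poisson(dens[ph] * area)
            xy = _sample_points(n, params, union, inside, rng)
            if ph == "Treg":
                for p in xy:
                    treg_slots.append((compartment, p))
                continue
            ki67_p = params.ki67_fraction_tcell if ph in ("CD8 T cell", "CD4 T cell") else 0.0
            pdl1_p = params.pdl1_fraction_myeloid if ph in ("PMN", "Macrophage") else 0.0
            add_cells(xy, compartment, ph, MARKERS[ph], ki67_p, pdl1_p,
                      _IMMUNE_DIAMETER, (0.9, 0.04))

    # non-immune stromal cells (fibroblast-like: large, not rounded)
    n_other = rng.poisson(params.stromal_other_density * stroma_mm2)
    add_cells(_sample_points(n_other, params, union, False, rng), "stroma", "other",
              MARKERS["other"], 0.05, 0.0, _OTHER_DIAMETER, (0.55, 0.1))

    # Tregs: resample positions violating the exclusion radius around
    # proliferating T cells; marginal compartment densities are preserved
    # approximately because only violating draws are replaced
    r = params.treg_exclusion_radius_um
    ki67_t = np.array(
        [[c["x_um"], c["y_um"]] for c in records
         if c["phenotype"] in ("CD8 T cell", "CD4 T cell") and c["ki67"]]
    )
    tree = None
    if r > 0 and len(ki67_t):
        from scipy.spatial import cKDTree

        tree = cKDTree(ki67_t)
    accepted = []
    for compartment, p in treg_slots:
        placed = None
        cand = p
        for _ in range(TREG_PLACEMENT_ATTEMPTS):
            if tree is None or tree.query(cand)[0] >= r:
                placed = cand
                break
            cand = _single_point(params, union, compartment == "tumor", rng)
            if cand is None:
                break
        if placed is not None:
            accepted.append((compartment, placed))
    for compartment in ("stroma", "tumor"):
        xy = np.array([p for c, p in accepted if c == compartment]).reshape(-1, 2)
        add_cells(xy, compartment, "Treg", MARKERS["Treg"], 0.0, 0.0,
                  _IMMUNE_DIAMETER, (0.9, 0.04))

    cells = pd.DataFrame.from_records(records)
    if len(cells) == 0:
        cells = pd.DataFrame(columns=[c for c in CELL_COLUMNS if c != "cell_id"])
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(len(cells))])
    return SlideSample(cells[list(CELL_COLUMNS)], tumor_mm2, stroma_mm2)


# ---------------------------------------------------------------------------
# caller noise


def _default_sensitivity():
    return {"LoFreq": 0.94, "MuSE": 0.92, "Mutect2": 0.97, "Strelka2": 0.95}


def _default_false_calls():
    return {"LoFreq": 8.0, "MuSE": 5.0, "Mutect2": 4.0, "Strelka2": 6.0}


@dataclass(frozen=True)
class CallerNoiseParams:
    """Per-caller detection sensitivity and mean private false-call count."""

    sensitivity: dict = field(default_factory=_default_sensitivity)
    false_call_mean: dict = field(default_factory=_default_false_calls)
    vaf_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for c in SNV_CALLERS:
            s = self.sensitivity.get(c)
            if s is None or not 0 <= s <= 1:
                raise ParameterError(f"sensitivity for {c} must be in [0, 1]")
            if self.false_call_mean.get(c, 0) < 0:
                raise ParameterError("false_call_mean must be >= 0")


@dataclass(frozen=True)
class SomaticVariant:
    """A planted truth variant with its coding consequence."""

    key: VariantKey
    vaf: float
    gene: str
    consequence: neo.ProteinConsequence
    present_pretreatment: bool = True


_BASES = "ACGT"


def _random_snv_key(rng, used: set) -> VariantKey:
    while True:
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1, 100_000_000))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        k = VariantKey(chrom, pos, str(ref), str(alt))
        if k not in used:
            used.add(k)
            return k


def _random_indel_key(rng, used: set) -> VariantKey:
    while True:
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1, 100_000_000))
        anchor = str(rng.choice(list(_BASES)))
        ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            k = VariantKey(chrom, pos, anchor, anchor + ins)  # insertion
        else:
            k = VariantKey(chrom, pos, anchor + ins, anchor)  # deletion
        if k not in used:
            used.add(k)
            return k


def generate_caller_callsets(
    truth: Sequence[SomaticVariant], noise: CallerNoiseParams, seed
) -> tuple[dict, dict]:
    """Per-caller call sets: truth thinned by sensitivity plus private false calls.

    Returns ``(snv_callsets, indel_callsets)`` keyed by caller name. The
    SNV ensemble is LoFreq/MuSE/Mutect2/Strelka2; MuSE emits no indels, so
    the indel ensemble is the remaining three callers.
    """
    rng = as_rng(seed)
    keys = [v.key for v in truth]
    if len(set(keys)) != len(keys):
        raise ParameterError("truth variants must have distinct keys")
    used = set(keys)
    snv_sets, indel_sets = {}, {}
    for caller in SNV_CALLERS:
        sens = noise.sensitivity[caller]
        calls: dict[VariantKey, float] = {}
        for v in truth:
            if not v.key.is_snv and caller not in INDEL_CALLERS:
                continue
            if rng.random() < sens:
                calls[v.key] = float(np.clip(rng.normal(v.vaf, noise.vaf_noise_sd), 0.01, 1.0))
        n_false = rng.poisson(noise.false_call_mean.get(caller, 0.0))
        for _ in range(n_false):
            make = _random_snv_key if (caller not in INDEL_CALLERS or rng.random() < 0.8) \
                else _random_indel_key
            calls[make(rng, used)] = float(rng.uniform(0.02, 0.2))
        snv_sets[caller] = CallerCallSet(caller, {k: f for k, f in calls.items() if k.is_snv})
        if caller in INDEL_CALLERS:
            indel_sets[caller] = CallerCallSet(
                caller, {k: f for k, f in calls.items() if not k.is_snv}
            )
    return snv_sets, indel_sets


# ---------------------------------------------------------------------------
# cohort-level parameters


@dataclass(frozen=True)
class PathologyParams:
    slides_per_patient: int = 3
    bed_area_mean_mm2: float = 120.0
    bed_area_sd_mm2: float = 40.0
    responder_ptr_range: tuple = (50.0, 70.0)
    nonresponder_ptr_range: tuple = (3.0, 49.0)
    ln_positive_prob: float = 0.25
    ln_suspicious_n0_prob: float = 0.35


@dataclass(frozen=True)
class VariantParams:
    n_genes: int = 60
    protein_length_range: tuple = (100, 400)
    mutation_count_mean: float = 60.0
    vaf_beta: tuple = (2.0, 5.0)
    tpm_log_mean: float = 1.0
    tpm_log_sigma: float = 1.5
    frameshift_fraction: float = 0.08
    synonymous_fraction: float = 0.10
    pretreatment_fraction: float = 0.95
    strong_binder_fraction: float = 0.25
    n_hla_alleles: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.strong_binder_fraction <= 1:
            raise ParameterError("strong_binder_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ElispotParams:
    """Spot-count model: overdispersed (negative binomial) duplicate counts.

    Responders carry a larger fraction of truly immunogenic synthesized
    peptides; immunogenic peptides get post-treatment means inflated by
    ``post_inflation_mean`` and are detectable pretreatment with
    probability ``pre_detected_fraction``.
    """

    n_assayed_patients: int = 12
    baseline_spot_mean: float = 0.5
    immunogenic_pre_mean: float = 3.0
    post_inflation_mean: float = 25.0
    nb_dispersion: float = 4.0
    immunogenic_fraction_responder: float = 0.45
    immunogenic_fraction_nonresponder: float = 0.05
    pre_detected_fraction: float = 0.5
    cef_positive_fraction: float = 0.5
    cef_mean: float = 25.0
    control_mean: float = 60.0


_HLA_POOL = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01", "HLA-A*24:02",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*35:01", "HLA-B*44:02",
    "HLA-C*04:01", "HLA-C*07:01", "HLA-C*07:02",
)


def _responder_pre_slide() -> SlidePatternParams:
    # low pretreatment stromal myeloid density predicts response
    return SlidePatternParams(
        stromal_densities={"CD8 T cell": 200.0, "CD4 T cell": 150.0, "Treg": 80.0,
                           "PMN": 60.0, "Macrophage": 50.0},
    )


def _responder_post_slide() -> SlidePatternParams:
    # CD8 influx into the parenchyma, stromal Treg loss, exclusion collapse
    return SlidePatternParams(
        intratumoral_densities={"CD8 T cell": 240.0, "CD4 T cell": 60.0, "Treg": 10.0,
                                "PMN": 60.0, "Macrophage": 75.0},
        stromal_densities={"CD8 T cell": 260.0, "CD4 T cell": 160.0, "Treg": 30.0,
                           "PMN": 60.0, "Macrophage": 50.0},
        treg_exclusion_radius_um=0.0,
        ki67_fraction_tumor=0.3,
        ki67_fraction_tcell=0.35,
    )


def _nonresponder_pre_slide() -> SlidePatternParams:
    return SlidePatternParams(
        stromal_densities={"CD8 T cell": 200.0, "CD4 T cell": 150.0, "Treg": 80.0,
                           "PMN": 200.0, "Macrophage": 160.0},
    )


def _nonresponder_post_slide() -> SlidePatternParams:
    return SlidePatternParams(
        stromal_densities={"CD8 T cell": 210.0, "CD4 T cell": 150.0, "Treg": 75.0,
                           "PMN": 200.0, "Macrophage": 160.0},
        intratumoral_densities={"CD8 T cell": 70.0, "CD4 T cell": 45.0, "Treg": 35.0,
                                "PMN": 55.0, "Macrophage": 70.0},
        ki67_fraction_tcell=0.3,
    )


@dataclass(frozen=True)
class CohortParams:
    n_patients: int = 14
    responder_fraction: float = 5 / 14
    responder_pre: SlidePatternParams = field(default_factory=_responder_pre_slide)
    responder_post: SlidePatternParams = field(default_factory=_responder_post_slide)
    nonresponder_pre: SlidePatternParams = field(default_factory=_nonresponder_pre_slide)
    nonresponder_post: SlidePatternParams = field(default_factory=_nonresponder_post_slide)
    pathology: PathologyParams = field(default_factory=PathologyParams)
    variants: VariantParams = field(default_factory=VariantParams)
    caller_noise: CallerNoiseParams = field(default_factory=CallerNoiseParams)
    elispot: ElispotParams = field(default_factory=ElispotParams)
    recurrence_prob_nonresponder: float = 0.22
    max_synthesized_per_patient: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not 0 <= self.responder_fraction <= 1:
            raise ParameterError("responder_fraction must be in [0, 1]")


@dataclass
class PatientData:
    patient_id: str
    planted_responder: bool
    cells_pre: pd.DataFrame
    cells_post: pd.DataFrame
    mif_areas: dict  # timepoint -> {"tumor": mm2, "stroma": mm2}
    slide_areas: list
    ln_status: str  # "positive" | "suspicious_n0" | "negative"
    lesions: list
    truth_variants: list
    pretreatment_keys: set
    snv_callsets: dict
    indel_callsets: dict
    annotations: dict  # VariantKey -> VariantAnnotation
    tpm: dict  # gene -> TPM
    hla_alleles: list
    proteins: Mapping[str, str]
    synthesized_peptides: list
    recurrence_within_1yr: bool


@dataclass
class CohortDataset:
    params: CohortParams
    proteins: dict
    patients: list
    predictor: neo.SyntheticBindingPredictor
    elispot_plates: pd.DataFrame | None

    @property
    def planted_responders(self) -> set:
        return {p.patient_id for p in self.patients if p.planted_responder}

    def write(self, outdir) -> None:
        from . import io as nio

        nio.write_cohort(self, outdir)


def _generate_proteins(vp: VariantParams, rng) -> dict:
    lo, hi = vp.protein_length_range
    return {
        f"G{g:03d}": "".join(
            rng.choice(list(neo.AA_ALPHABET), size=int(rng.integers(lo, hi + 1)))
        )
        for g in range(1, vp.n_genes + 1)
    }


def _random_consequence(protein: str, rng, vp: VariantParams) -> neo.ProteinConsequence:
    p = int(rng.integers(1, len(protein) + 1))
    ref = protein[p - 1]
    u = rng.random()
    if u < vp.synonymous_fraction:
        return neo.ProteinConsequence("synonymous", p, ref_aa=ref, alt_aa=ref)
    if u < vp.synonymous_fraction + vp.frameshift_fraction:
        tail_len = 1 + int(rng.geometric(1 / 12.0))
        tail = "".join(rng.choice(list(neo.AA_ALPHABET), size=tail_len)) + "*"
        return neo.ProteinConsequence("frameshift", p, ref_aa=ref, tail=tail)
    alt = str(rng.choice([a for a in neo.AA_ALPHABET if a != ref]))
    return neo.ProteinConsequence("missense", p, ref_aa=ref, alt_aa=alt)


def _generate_truth_variants(vp: VariantParams, proteins: dict, rng) -> list:
    n = max(1, rng.poisson(vp.mutation_count_mean))
    genes = sorted(proteins)
    used: set = set()
    out = []
    for _ in range(n):
        gene = str(rng.choice(genes))
        cons = _random_consequence(proteins[gene], rng, vp)
        key = _random_indel_key(rng, used) if cons.kind == "frameshift" \
            else _random_snv_key(rng, used)
        vaf = float(np.clip(rng.beta(*vp.vaf_beta), 0.02, 1.0))
        out.append(SomaticVariant(
            key, vaf, gene, cons,
            present_pretreatment=bool(rng.random() < vp.pretreatment_fraction),
        ))
    return out


def _nb_counts(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with the given mean and shape (overdispersed)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_elispot_plate(
    patient_id: str,
    peptide_ids: Sequence[str],
    responder: bool,
    params: ElispotParams,
    rng,
) -> pd.DataFrame:
    """Duplicate spot counts for one patient's coculture plate.

    A seeded fraction of the synthesized peptides (larger for responders)
    is immunogenic: detectable post-treatment with inflated counts, and
    detectable pretreatment for half of them. Used both inside the cohort
    generator and on its own for ELISpot-level simulation studies.
    """
    rng = as_rng(rng)
    frac = (params.immunogenic_fraction_responder if responder
            else params.immunogenic_fraction_nonresponder)
    rows = []

    def add(condition, pre_mean, post_mean):
        pre = _nb_counts(rng, pre_mean, params.nb_dispersion, 2)
        post = _nb_counts(rng, post_mean, params.nb_dispersion, 2)
        rows.append({"patient_id": patient_id, "condition": condition, "timepoint": "pre",
                     "rep1": int(pre[0]), "rep2": int(pre[1])})
        rows.append({"patient_id": patient_id, "condition": condition, "timepoint": "post",
                     "rep1": int(post[0]), "rep2": int(post[1])})

    for pep in peptide_ids:
        immunogenic = rng.random() < frac
        if immunogenic:
            pre_mean = (params.immunogenic_pre_mean
                        if rng.random() < params.pre_detected_fraction else 0.0)
            add(pep, pre_mean, params.post_inflation_mean)
        else:
            add(pep, params.baseline_spot_mean / 2, params.baseline_spot_mean)
    cef_pos = rng.random() < params.cef_positive_fraction
    add(er.CEF_CONDITION, params.cef_mean if cef_pos else 0.2,
        params.cef_mean if cef_pos else 0.3)
    add(er.CONTROL_CONDITION, params.control_mean, params.control_mean)
    add(er.BACKGROUND_CONDITION, 0.2, 0.2)
    return pd.DataFrame(rows)


def _generate_patient(
    pid: str,
    responder: bool,
    params: CohortParams,
    proteins: dict,
    predictor,
    assay_elispot: bool,
    ss: np.random.SeedSequence,
) -> tuple[PatientData, pd.DataFrame | None]:
    streams = ss.spawn(7)
    rng_path, rng_lesion, rng_var, rng_call, rng_hla, rng_eli, rng_rec = (
        np.random.default_rng(s) for s in streams[:7]
    )
    pp, vp = params.pathology, params.variants

    pre_params = params.responder_pre if responder else params.nonresponder_pre
    post_params = params.responder_post if responder else params.nonresponder_post
    slide_pre = generate_cell_slide(pre_params, np.random.default_rng(ss.spawn(1)[0]))
    slide_post = generate_cell_slide(post_params, np.random.default_rng(ss.spawn(1)[0]))

    # pathology: identical viable fraction across a patient's slides makes the
    # pooled pTR equal the drawn target exactly, so class membership is exact
    lo, hi = pp.responder_ptr_range if responder else pp.nonresponder_ptr_range
    target_ptr = rng_path.uniform(lo, hi)
    viable_frac = 1.0 - target_ptr / 100.0
    slides = []
    for b in range(pp.slides_per_patient):
        bed = max(5.0, rng_path.normal(pp.bed_area_mean_mm2, pp.bed_area_sd_mm2))
        slides.append(SlideAreaRecord(pid, "primary", f"B{b+1}", bed * viable_frac, bed))
    u = rng_path.random()
    if u < pp.ln_positive_prob:
        ln_status = "positive"
        ln_lo, ln_hi = (60.0, 100.0) if responder else (5.0, 60.0)
        ln_ptr = rng_path.uniform(ln_lo, ln_hi)
        for b in range(2):
            bed = max(2.0, rng_path.normal(30.0, 10.0))
            slides.append(
                SlideAreaRecord(pid, "LN", f"LN{b+1}", bed * (1 - ln_ptr / 100.0), bed)
            )
    elif u < pp.ln_positive_prob + pp.ln_suspicious_n0_prob:
        ln_status = "suspicious_n0"
    else:
        ln_status = "negative"

    lesions = []
    pre_len = rng_lesion.uniform(20, 50)
    pre_wid = pre_len * rng_lesion.uniform(0.5, 1.0)
    factor = float(np.exp(rng_lesion.normal(0.18, 0.3)))
    lesions.append(LesionMeasurement(pid, "primary", "pre", pre_len, pre_wid))
    lesions.append(
        LesionMeasurement(pid, "primary", "post", pre_len * factor, pre_wid * factor)
    )
    if ln_status != "negative":
        ln_len = rng_lesion.uniform(10, 30)
        ln_wid = ln_len * rng_lesion.uniform(0.5, 1.0)
        ln_factor = float(np.exp(rng_lesion.normal(0.2, 0.3)))
        lesions.append(LesionMeasurement(pid, "LN", "pre", ln_len, ln_wid,
                                         suspicious_flag=True))
        lesions.append(LesionMeasurement(pid, "LN", "post", ln_len * ln_factor,
                                         ln_wid * ln_factor, suspicious_flag=True))

    truth = _generate_truth_variants(vp, proteins, rng_var)
    pretreatment_keys = {v.key for v in truth if v.present_pretreatment}
    snv_sets, indel_sets = generate_caller_callsets(truth, params.caller_noise, rng_call)
    annotations = {
        v.key: VariantAnnotation(v.gene, v.consequence.hgvs_p(), v.consequence)
        for v in truth
    }
    tpm = {g: float(np.exp(rng_var.normal(vp.tpm_log_mean, vp.tpm_log_sigma)))
           for g in sorted(proteins)}
    hla = sorted(rng_hla.choice(_HLA_POOL, size=vp.n_hla_alleles, replace=False))

    # the synthesis list the trial would have ordered: selection criteria
    # applied to the *truth* consensus (the generator plays the role of the
    # historical pipeline run)
    truth_consensus = [
        ConsensusVariant(v.key, frozenset(SNV_CALLERS if v.key.is_snv else INDEL_CALLERS),
                         v.vaf, gene=v.gene, protein_change=v.consequence.hgvs_p(),
                         consequence=v.consequence, tpm=tpm[v.gene],
                         present_pretreatment=v.present_pretreatment)
        for v in truth
    ]
    cands = neo.candidates_from_variants(truth_consensus, proteins, hla, predictor)
    selected = neo.select_candidates(
        neo.rank_candidates(cands), max_per_patient=params.max_synthesized_per_patient
    )
    synthesized = [c.peptide for c in selected]

    plate = None
    if assay_elispot and synthesized:
        plate = generate_elispot_plate(pid, synthesized, responder, params.elispot, rng_eli)

    recurrence = (not responder) and (rng_rec.random() < params.recurrence_prob_nonresponder)

    patient = PatientData(
        patient_id=pid,
        planted_responder=responder,
        cells_pre=slide_pre.cells,
        cells_post=slide_post.cells,
        mif_areas={
            "pre": {"tumor": slide_pre.tumor_area_mm2, "stroma": slide_pre.stroma_area_mm2},
            "post": {"tumor": slide_post.tumor_area_mm2, "stroma": slide_post.stroma_area_mm2},
        },
        slide_areas=slides,
        ln_status=ln_status,
        lesions=lesions,
        truth_variants=truth,
        pretreatment_keys=pretreatment_keys,
        snv_callsets=snv_sets,
        indel_callsets=indel_sets,
        annotations=annotations,
        tpm=tpm,
        hla_alleles=hla,
        proteins=proteins,
        synthesized_peptides=synthesized,
        recurrence_within_1yr=recurrence,
    )
    return patient, plate


def generate_patient_cohort(params: CohortParams) -> CohortDataset:
    """Generate a complete synthetic cohort.

    Exactly ``round(n_patients x responder_fraction)`` patients are drawn
    as responders (assignment is a seeded permutation, so it is
    deterministic in the cohort seed); responders receive pTR >= 50 by
    construction, and every planted effect described in the module
    docstring follows the patient's class.
    """
    root = np.random.SeedSequence(params.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    n = params.n_patients
    n_resp = round_half_away(params.responder_fraction * n)
    order = assign_rng.permutation(n)
    responder_flags = np.zeros(n, dtype=bool)
    responder_flags[order[:n_resp]] = True

    # TIL cultures succeed for a fixed number of patients; the unassayed
    # ones are taken from the non-responders (matching the assayed PR split)
    n_assayed = min(params.elispot.n_assayed_patients, n)
    n_drop = n - n_assayed
    non_responder_idx = [i for i in range(n) if not responder_flags[i]]
    dropped = set(non_responder_idx[-n_drop:]) if n_drop else set()

    proteins = _generate_proteins(params.variants, np.random.default_rng(root.spawn(1)[0]))
    predictor = neo.SyntheticBindingPredictor(
        seed=int(params.seed) % 2**31, strong_fraction=params.variants.strong_binder_fraction
    )

    patients, plates = [], []
    patient_streams = root.spawn(n)
    for i in range(n):
        pid = f"P{i+1:02d}"
        patient, plate = _generate_patient(
            pid, bool(responder_flags[i]), params, proteins, predictor,
            assay_elispot=i not in dropped, ss=patient_streams[i],
        )
        patients.append(patient)
        if plate is not None:
            plates.append(plate)
    plates_df = pd.concat(plates, ignore_index=True) if plates else None
    return CohortDataset(params, proteins, patients, predictor, plates_df)
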