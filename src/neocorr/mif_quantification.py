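"""Multispectral-immunofluorescence quantification.

Works on per-cell tables (one row per segmented cell) carrying boolean
marker states, a tissue compartment ("tumor" parenchyma vs "stroma"), a
scaled intensity bin in {0, 1, 2, 3}, a diameter and a roundness value.

Provides phenotype gating against a mutually exclusive marker panel,
compartment cell densities (cells/mm^2), the intensity-weighted H-score
(0-300), the stromal immune-cell fraction, and pre/post log2 fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, ParameterError

#: boolean marker columns expected on a cell table
MARKER_COLUMNS = (
    "cd3",
    "cd8",
    "cd4",
    "foxp3",
    "ki67",
    "pdl1",
    "ck",
    "pmn_marker",
    "mac_marker",
)

COMPARTMENTS = ("tumor", "stroma")


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A phenotype gate: required-positive and required-negative markers."""

    name: str
    positive: frozenset
    negative: frozenset = frozenset()

    def __post_init__(self) -> None:
        bad = (set(self.positive) | set(self.negative)) - set(MARKER_COLUMNS)
        if bad:
            raise ConfigurationError(f"unknown markers in {self.name!r}: {sorted(bad)}")
        if set(self.positive) & set(self.negative):
            raise ConfigurationError(f"{self.name!r} requires a marker both + and -")

    def matches(self, cells: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=cells.index)
        for m in self.positive:
            mask &= cells[m].astype(bool)
        for m in self.negative:
            mask &= ~cells[m].astype(bool)
        return mask


def _pheno(name, pos, neg=()):
    return PhenotypeDefinition(name, frozenset(pos), frozenset(neg))


#: default panel: FoxP3- cytotoxic/helper T cells, Tregs, myeloid cells,
#: cytokeratin+ tumor cells. Pairwise mutually exclusive.
DEFAULT_PANEL = (
    _pheno("CD8 T cell", ("cd3", "cd8"), ("foxp3",)),
    _pheno("CD4 T cell", ("cd3", "cd4"), ("foxp3", "cd8")),
    _pheno("Treg", ("cd3", "cd4", "foxp3")),
    _pheno("PMN", ("pmn_marker",), ("cd3", "ck", "mac_marker")),
    _pheno("Macrophage", ("mac_marker",), ("cd3", "ck", "pmn_marker")),
    _pheno("Tumor cell", ("ck",), ("cd3",)),
)

MYELOID_PHENOTYPES = ("PMN", "Macrophage")
TCELL_PHENOTYPES = ("CD8 T cell", "CD4 T cell", "Treg")


@dataclass(frozen=True)
class DensityResult:
    phenotype: str
    compartment: str
    count: int
    area_mm2: float

    @property
    def density(self) -> float:
        return self.count / self.area_mm2


def _check_exclusive(defs: Sequence[PhenotypeDefinition]) -> None:
    """Two gates overlap iff some marker assignment satisfies both, i.e.
    neither gate requires positive a marker the other requires negative."""
    for i, a in enumerate(defs):
        for b in defs[i + 1 :]:
            if not (a.positive & b.negative) and not (b.positive & a.negative):
                raise ConfigurationError(
                    f"phenotype definitions {a.name!r} and {b.name!r} can overlap"
                )


def assign_phenotypes(
    cells: pd.DataFrame, defs: Sequence[PhenotypeDefinition] = DEFAULT_PANEL
) -> pd.DataFrame:
    """Return a copy of ``cells`` with a ``phenotype`` column.

    Each cell receives the label of the single matching definition, or
    ``"other"`` when no gate matches. Definitions must be mutually exclusive.
    """
    _check_exclusive(tuple(defs))
    out = cells.copy()
    label = pd.Series("other", index=out.index)
    for d in defs:
        label[d.matches(out)] = d.name
    out["phenotype"] = label
    return out


def cell_density(
    cells: pd.DataFrame, phenotype: str, compartment: str, area_mm2: float
) -> DensityResult:
    """Cells of ``phenotype`` per mm^2 of ``compartment`` ("whole" = slide).

    Duplicated rows (double-imported cells) are dropped before counting.
    """
    if not area_mm2 > 0:
        raise DegenerateInputError("compartment area must be positive")
    if compartment not in COMPARTMENTS + ("whole",):
        raise ParameterError(f"unknown compartment {compartment!r}")
    sub = cells.drop_duplicates()
    sub = sub[sub["phenotype"] == phenotype]
    if compartment != "whole":
        sub = sub[sub["compartment"] == compartment]
    return DensityResult(phenotype, compartment, int(len(sub)), float(area_mm2))


def h_score(pct_1plus: float, pct_2plus: float, pct_3plus: float) -> float:
    """Intensity-weighted expression score on [0, 300].

    ``(% 1+ cells x 1) + (% 2+ cells x 2) + (% 3+ cells x 3)``; the three
    percentages are of all cells in the population, so they sum to <= 100.
    """
    fractions = (pct_1plus, pct_2plus, pct_3plus)
    for f in fractions:
        if not (math.isfinite(f) and f >= 0):
            raise ParameterError("bin percentages must be finite and >= 0")
    if sum(fractions) > 100 + 1e-9:
        raise ParameterError("bin percentages sum to more than 100")
    return pct_1plus * 1 + pct_2plus * 2 + pct_3plus * 3


def h_score_from_cells(cells: pd.DataFrame, marker: str) -> float:
    """H-score of ``marker`` over a cell population.

    Marker-negative cells count as intensity 0; marker-positive cells
    contribute their scaled intensity bin (cells recorded in bin 0 while
    marker-positive are treated as 1+).
    """
    if len(cells) == 0:
        return float("nan")
    positive = cells[marker].astype(bool).to_numpy()
    bins = cells["intensity_bin"].to_numpy().astype(int)
    eff = np.where(positive, np.maximum(bins, 1), 0)
    pct = [100.0 * np.mean(eff == k) for k in (1, 2, 3)]
    return h_score(*pct)


def stromal_immune_fraction(
    stromal_cells: pd.DataFrame,
    roundness_threshold: float = 0.8,
    max_diameter_um: float = 15.0,
) -> float:
    """Fraction of stromal cells that look immune: cytokeratin-negative,
    rounded (roundness >= threshold) and no larger than ``max_diameter_um``.

    Returns NaN for an empty stromal compartment.
    """
    if len(stromal_cells) == 0:
        return float("nan")
    ok = (
        ~stromal_cells["ck"].astype(bool)
        & (stromal_cells["roundness"] >= roundness_threshold)
        & (stromal_cells["diameter_um"] <= max_diameter_um)
    )
    return float(ok.mean())


def _auto_eps(pre: float, post: float, pseudocount: float | None) -> float:
    if pseudocount is not None:
        return float(pseudocount)
    # one unit (cell/mm^2 or H-score point) only when a side is exactly zero
    return 1.0 if (pre == 0 or post == 0) else 0.0


def log2_fc(pre: float, post: float, pseudocount: float | None = None) -> float:
    """log2 fold change post vs pre.

    With ``pseudocount=None`` a pseudocount of 1 is applied only when either
    value is exactly zero, keeping the fold change finite without perturbing
    nonzero measurements.
    """
    if pre < 0 or post < 0:
        raise ParameterError("log2_fc requires nonnegative values")
    eps = _auto_eps(pre, post, pseudocount)
    return float(np.log2((post + eps) / (pre + eps)))


def cd8_treg_ratio(
    cd8_density: float, treg_density: float, pseudocount: float | None = None
) -> float:
    """CD8 T cell to Treg density ratio with the same zero-guard rule."""
    if cd8_density < 0 or treg_density < 0:
        raise ParameterError("densities must be nonnegative")
    eps = _auto_eps(cd8_density, treg_density, pseudocount)
    return float((cd8_density + eps) / (treg_density + eps))


def density_table(
    cells: pd.DataFrame,
    areas: dict,
    phenotypes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Phenotype x compartment density table for one slide.

    ``areas`` maps compartment -> mm^2 and must contain "tumor" and
    "stroma"; the whole-slide area is their sum.
    """
    if phenotypes is None:
        phenotypes = sorted(cells["phenotype"].unique())
    rows = []
    whole = areas["tumor"] + areas["stroma"]
    for ph in phenotypes:
        for comp, area in (("tumor", areas["tumor"]), ("stroma", areas["stroma"]), ("whole", whole)):
            if area <= 0:
                rows.append({"phenotype": ph, "compartment": comp, "count": 0,
                             "area_mm2": area, "density": float("nan")})
                continue
            r = cell_density(cells, ph, comp, area)
            rows.append({"phenotype": ph, "compartment": comp, "count": r.count,
                         "area_mm2": r.area_mm2, "density": r.density})
    return pd.DataFrame(rows)
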