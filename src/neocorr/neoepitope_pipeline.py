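"""Neoepitope candidate enumeration, ranking and selection.

From each nonsilent coding variant the mutant protein context is built and
every 9-mer window overlapping an altered residue is enumerated; windows
identical to a wild-type 9-mer of the same protein are discarded (they are
not neoepitopes). Candidates are scored against the patient's HLA class I
alleles through a pluggable binding-predictor interface, ranked by RNA
expression and variant allele frequency, and selected for synthesis by
three criteria: present in the pretreatment sample, predicted IC50 of
200 nM or less, and expression of at least 4 TPM.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .errors import ParameterError
from .variant_consensus import ConsensusVariant, VariantKey, log2_tpm

log = logging.getLogger(__name__)

PEPTIDE_LENGTH = 9
IC50_SELECT_NM = 200.0
TPM_SELECT = 4.0
IC50_PREDICTED_NM = 500.0  # "predicted neoepitope" tally threshold
DEFAULT_MAX_PER_PATIENT = 12

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level consequence of a coding variant.

    ``kind`` is one of missense / inframe_ins / inframe_del / frameshift /
    stop_gained / synonymous. ``position`` is the 1-based residue index in
    the wild-type protein where the change starts. ``tail`` holds the novel
    frameshift translation up to (and possibly including) the new stop.
    """

    kind: str
    position: int
    ref_aa: str = ""
    alt_aa: str = ""
    inserted: str = ""
    deleted_length: int = 0
    tail: str = ""

    def hgvs_p(self) -> str:
        if self.kind == "missense":
            return f"p.{self.ref_aa}{self.position}{self.alt_aa}"
        if self.kind == "frameshift":
            return f"p.{self.ref_aa}{self.position}fs"
        if self.kind == "stop_gained":
            return f"p.{self.ref_aa}{self.position}*"
        if self.kind == "inframe_ins":
            return f"p.{self.position}ins{self.inserted}"
        if self.kind == "inframe_del":
            return f"p.{self.position}del{self.deleted_length}"
        return f"p.{self.ref_aa}{self.position}="


@dataclass(frozen=True)
class ProteinContext:
    gene: str
    wildtype_sequence: str
    mutant_sequence: str
    altered_positions: frozenset  # 1-based indices into mutant_sequence

    def __post_init__(self) -> None:
        for seq in (self.wildtype_sequence, self.mutant_sequence):
            if set(seq) - _AA_SET:
                raise ParameterError("sequence contains non-amino-acid letters")
        if self.altered_positions and (
            min(self.altered_positions) < 1
            or max(self.altered_positions) > len(self.mutant_sequence)
        ):
            raise ParameterError("altered positions outside mutant sequence")

    @property
    def is_empty(self) -> bool:
        return not self.altered_positions


def _strip_tail(tail: str) -> str:
    stop = tail.find("*")
    return tail if stop < 0 else tail[:stop]


def build_mutant_context(
    wildtype: str, consequence: ProteinConsequence, gene: str = ""
) -> ProteinContext:
    """Mutant protein sequence and altered residue set for one variant.

    Synonymous changes are rejected (not nonsilent); a variant creating an
    immediate stop yields the empty-context sentinel (no altered residues,
    so no 9-mers are enumerated).
    """
    kind, p = consequence.kind, consequence.position
    if not 1 <= p <= len(wildtype):
        raise ParameterError(f"position {p} outside protein of length {len(wildtype)}")
    if kind == "synonymous":
        raise ParameterError("synonymous variant is not nonsilent")
    if kind == "missense":
        ref, alt = consequence.ref_aa, consequence.alt_aa
        if wildtype[p - 1] != ref:
            raise ParameterError(f"reference residue mismatch at {p}: {wildtype[p-1]}!={ref}")
        if alt == ref:
            raise ParameterError("missense with identical residue is synonymous")
        mutant = wildtype[: p - 1] + alt + wildtype[p:]
        altered = frozenset({p})
    elif kind == "stop_gained":
        return ProteinContext(gene, wildtype, wildtype[: p - 1], frozenset())
    elif kind == "inframe_ins":
        ins = consequence.inserted
        mutant = wildtype[:p] + ins + wildtype[p:]
        altered = frozenset(range(p, min(p + len(ins) + 2, len(mutant) + 1)))
    elif kind == "inframe_del":
        k = consequence.deleted_length
        if k < 1 or p - 1 + k > len(wildtype):
            raise ParameterError("deletion extends past protein end")
        mutant = wildtype[: p - 1] + wildtype[p - 1 + k :]
        altered = frozenset(q for q in (p - 1, p) if 1 <= q <= len(mutant))
    elif kind == "frameshift":
        tail = _strip_tail(consequence.tail)
        mutant = wildtype[: p - 1] + tail
        altered = frozenset(range(p, len(mutant) + 1))
    else:
        raise ParameterError(f"unknown consequence kind {kind!r}")
    return ProteinContext(gene, wildtype, mutant, altered)


def enumerate_9mers(context: ProteinContext) -> list[str]:
    """All novel 9-mers of the mutant protein.

    Sliding windows over the mutant sequence that overlap at least one
    altered residue, minus any peptide present among the wild-type 9-mers
    of the same protein, deduplicated keeping leftmost-first order.
    """
    mut, wt = context.mutant_sequence, context.wildtype_sequence
    L = len(mut)
    if L < PEPTIDE_LENGTH or context.is_empty:
        return []
    wt_9mers = {wt[i : i + PEPTIDE_LENGTH] for i in range(len(wt) - PEPTIDE_LENGTH + 1)}
    altered = context.altered_positions
    out, seen = [], set()
    for s in range(1, L - PEPTIDE_LENGTH + 2):  # 1-based window starts
        if not any((s <= q <= s + PEPTIDE_LENGTH - 1) for q in altered):
            continue
        pep = mut[s - 1 : s + PEPTIDE_LENGTH - 1]
        if pep in wt_9mers or pep in seen:
            continue
        seen.add(pep)
        out.append(pep)
    return out


class BindingPredictor(Protocol):
    """Deterministic (peptide, HLA allele) -> predicted IC50 in nM."""

    def __call__(self, peptide: str, hla_allele: str) -> float: ...


class TableBindingPredictor:
    """File/dict-backed IC50 lookup; raises KeyError for unknown pairs."""

    def __init__(self, table: Mapping[tuple, float]):
        self._table = dict(table)

    def __call__(self, peptide: str, hla_allele: str) -> float:
        return self._table[(peptide, hla_allele)]

    @classmethod
    def from_tsv(cls, path) -> "TableBindingPredictor":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls({(r.peptide, r.allele): float(r.ic50_nm) for r in df.itertuples()})


class SyntheticBindingPredictor:
    """Hash-seeded stand-in for an MHC binding predictor.

    Deterministic in (peptide, allele, seed): a fixed fraction of pairs are
    strong binders with IC50 uniform on (10, 200]; the rest are log-uniform
    on (200, 50000]. This reproduces the *distributional* role of a real
    predictor (a controllable strong-binder rate) with none of its biology.
    """

    def __init__(self, seed: int = 0, strong_fraction: float = 0.25):
        if not 0 <= strong_fraction <= 1:
            raise ParameterError("strong_fraction must be in [0, 1]")
        self.seed = int(seed)
        self.strong_fraction = float(strong_fraction)

    def _unit(self, *parts: str) -> float:
        h = hashlib.blake2b("|".join(parts).encode(), digest_size=8).digest()
        return int.from_bytes(h, "big") / 2**64

    def __call__(self, peptide: str, hla_allele: str) -> float:
        u = self._unit("class", str(self.seed), peptide, hla_allele)
        v = self._unit("value", str(self.seed), peptide, hla_allele)
        if u < self.strong_fraction:
            return 10.0 + v * 190.0
        return float(200.0 * (250.0**v))


@dataclass(frozen=True)
class NeoepitopeCandidate:
    peptide: str
    variant_key: VariantKey
    gene: str
    hla_allele: str
    ic50_nm: float
    tpm: float
    vaf: float
    present_pretreatment: bool
    rank_score: float = float("nan")
    selected: bool = False

    def __post_init__(self) -> None:
        if len(self.peptide) != PEPTIDE_LENGTH:
            raise ParameterError("candidate peptide must be a 9-mer")


def candidates_from_variants(
    variants: Sequence[ConsensusVariant],
    proteins: Mapping[str, str],
    hla_alleles: Sequence[str],
    predictor: BindingPredictor,
) -> list[NeoepitopeCandidate]:
    """Enumerate candidates for every annotated nonsilent variant.

    Each peptide is scored against all patient HLA class I alleles and
    keeps its best (lowest) IC50. Variants without annotation, synonymous
    variants and predictor failures are skipped (the latter with a logged
    warning).
    """
    out = []
    for v in variants:
        if v.consequence is None or v.gene is None or v.gene not in proteins:
            continue
        try:
            ctx = build_mutant_context(proteins[v.gene], v.consequence, gene=v.gene)
        except ParameterError:
            continue  # synonymous or inconsistent annotation
        for pep in enumerate_9mers(ctx):
            best_allele, best_ic50 = None, np.inf
            for allele in hla_alleles:
                try:
                    ic50 = float(predictor(pep, allele))
                except Exception:  # noqa: BLE001 - predictor contract violation
                    log.warning("predictor failed for %s / %s; peptide dropped", pep, allele)
                    continue
                if ic50 < best_ic50:
                    best_allele, best_ic50 = allele, ic50
            if best_allele is None:
                continue
            out.append(
                NeoepitopeCandidate(
                    peptide=pep,
                    variant_key=v.key,
                    gene=v.gene,
                    hla_allele=best_allele,
                    ic50_nm=best_ic50,
                    tpm=v.tpm,
                    vaf=v.vaf,
                    present_pretreatment=bool(v.present_pretreatment),
                )
            )
    return out


def rank_candidates(
    candidates: Sequence[NeoepitopeCandidate],
    score: Callable[[float, float], float] | None = None,
) -> list[NeoepitopeCandidate]:
    """Order candidates by expression and allele frequency.

    Default combiner: ``rank_score = log2(TPM + 1) x VAF`` (monotone in both
    ranking keys); ties broken by ascending IC50, then peptide lexicographic
    order. The combiner is configurable via ``score(tpm, vaf)``.
    """
    if score is None:
        score = lambda tpm, vaf: log2_tpm(tpm) * vaf  # noqa: E731
    scored = [replace(c, rank_score=float(score(c.tpm, c.vaf))) for c in candidates]
    return sorted(scored, key=lambda c: (-c.rank_score, c.ic50_nm, c.peptide))


def select_candidates(
    ranked: Sequence[NeoepitopeCandidate],
    max_per_patient: int = DEFAULT_MAX_PER_PATIENT,
    ic50_max_nm: float = IC50_SELECT_NM,
    tpm_min: float = TPM_SELECT,
    tpm_on_log_scale: bool = False,
) -> list[NeoepitopeCandidate]:
    """Apply the three synthesis-selection criteria, preserving rank order.

    Keeps candidates (a) present in the pretreatment sample, (b) with IC50
    <= 200 nM, (c) with TPM >= 4 (raw TPM by default; set
    ``tpm_on_log_scale`` to threshold log2(TPM+1) instead), truncated to
    ``max_per_patient`` best-ranked peptides.
    """
    kept = []
    for c in ranked:
        expr = log2_tpm(c.tpm) if tpm_on_log_scale else c.tpm
        if c.present_pretreatment and c.ic50_nm <= ic50_max_nm and expr >= tpm_min:
            kept.append(replace(c, selected=True))
        if len(kept) >= max_per_patient:
            break
    return kept


def count_predicted(candidates: Sequence[NeoepitopeCandidate],
                    ic50_below_nm: float = IC50_PREDICTED_NM) -> int:
    """Distinct peptides predicted to bind below the given IC50."""
    return len({c.peptide for c in candidates if c.ic50_nm < ic50_below_nm})
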