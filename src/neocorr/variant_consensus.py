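"""Ensemble consensus of somatic variant calls.

Somatic SNVs are retained when detected by at least 3 of the 4 callers
LoFreq, MuSE, Mutect2 and Strelka2; small indels when detected by at least
2 of the 3 indel-capable callers (MuSE emits no indels). Variant identity
is the exact (chrom, pos, ref, alt) key after normalization, so the voting
rule is well defined across caller-specific representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import ConfigurationError, ParameterError

SNV_CALLERS = ("LoFreq", "MuSE", "Mutect2", "Strelka2")
INDEL_CALLERS = ("LoFreq", "Mutect2", "Strelka2")
SNV_MIN_SUPPORT = 3
INDEL_MIN_SUPPORT = 2
PRIMARY_VAF_CALLER = "Mutect2"


class VariantKey(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def vtype(self) -> str:
        return "SNV" if self.is_snv else "INDEL"


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonical variant key: trim shared prefix bases, then shared suffix.

    Left-alignment against a reference sequence is out of reach without the
    genome; prefix-then-suffix trimming (keeping at least one base per
    allele) resolves the common representational differences between
    callers, e.g. padded alleles and anchor-base conventions.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ParameterError("ref and alt must be nonempty")
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return VariantKey(chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class CallerCallSet:
    """One caller's variant calls: key -> VAF (NaN when not reported)."""

    caller: str
    calls: Mapping[VariantKey, float]

    def __post_init__(self) -> None:
        if self.caller not in SNV_CALLERS:
            raise ConfigurationError(f"unknown caller {self.caller!r}")
        if self.caller == "MuSE" and any(not k.is_snv for k in self.calls):
            raise ConfigurationError("MuSE emits no indels")

    def keys(self):
        return self.calls.keys()


@dataclass(frozen=True)
class ConsensusVariant:
    key: VariantKey
    supporting_callers: frozenset
    vaf: float
    gene: str | None = None
    protein_change: str | None = None
    consequence: object = None  # ProteinConsequence once annotated
    tpm: float = float("nan")
    present_pretreatment: bool | None = None

    @property
    def n_support(self) -> int:
        return len(self.supporting_callers)


def _consensus(
    callsets: Sequence[CallerCallSet],
    expected_callers: tuple,
    min_support: int,
    want_snv: bool,
) -> list[ConsensusVariant]:
    names = [c.caller for c in callsets]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate caller in {names}")
    if set(names) != set(expected_callers):
        raise ConfigurationError(
            f"expected callers {sorted(expected_callers)}, got {sorted(names)}"
        )
    by_caller = {c.caller: c for c in callsets}
    support: dict[VariantKey, list[str]] = {}
    for c in callsets:
        for k in c.keys():
            if k.is_snv == want_snv:
                support.setdefault(k, []).append(c.caller)
    out = []
    for k in sorted(support):
        callers = support[k]
        if len(callers) < min_support:
            continue
        if PRIMARY_VAF_CALLER in callers:
            vaf = float(by_caller[PRIMARY_VAF_CALLER].calls[k])
        else:
            vaf = float(np.mean([by_caller[c].calls[k] for c in callers]))
        out.append(ConsensusVariant(k, frozenset(callers), vaf))
    return out


def consensus_snvs(callsets: Sequence[CallerCallSet]) -> list[ConsensusVariant]:
    """SNVs detected by >=3 of the 4 SNV callers, sorted by key."""
    return _consensus(callsets, SNV_CALLERS, SNV_MIN_SUPPORT, want_snv=True)


def consensus_indels(callsets: Sequence[CallerCallSet]) -> list[ConsensusVariant]:
    """Indels detected by >=2 of the 3 indel callers, sorted by key."""
    return _consensus(callsets, INDEL_CALLERS, INDEL_MIN_SUPPORT, want_snv=False)


def log2_tpm(tpm) -> float:
    """log2(TPM + 1) expression transform (scalar or array)."""
    arr = np.asarray(tpm, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("TPM values must be nonnegative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(tpm) or arr.ndim == 0 else out


@dataclass(frozen=True)
class VariantAnnotation:
    """Coding consequence attached to a consensus variant."""

    gene: str
    protein_change: str
    consequence: object  # neoepitope_pipeline.ProteinConsequence


def attach_annotations(
    variants: Sequence[ConsensusVariant],
    annotations: Mapping[VariantKey, VariantAnnotation],
    tpm_by_gene: Mapping[str, float],
    pretreatment_keys: set,
) -> list[ConsensusVariant]:
    """Join gene/protein-change/expression onto consensus variants.

    Variants without an annotation (non-coding or false calls) are kept but
    left unannotated; downstream neoepitope enumeration skips them.
    """
    out = []
    for v in variants:
        ann = annotations.get(v.key)
        fields = dict(present_pretreatment=v.key in pretreatment_keys)
        if ann is not None:
            fields.update(
                gene=ann.gene,
                protein_change=ann.protein_change,
                consequence=ann.consequence,
                tpm=float(tpm_by_gene.get(ann.gene, float("nan"))),
            )
        out.append(replace(v, **fields))
    return out
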