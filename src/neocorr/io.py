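"""File formats: cell CSVs, VCF 4.2 call sets, FASTA proteins, TSV tables.

A cohort directory written by :func:`write_cohort` contains everything the
analysis stages read back::

    manifest.json                cohort parameters, patient metadata
    cells/<pid>_<tp>.csv         segmented-cell tables
    pathology/slide_areas.csv    viable/bed areas per slide
    pathology/lesions.csv        bidimensional lesion measurements
    variants/<pid>/<caller>.{snv,indel}.vcf
    variants/<pid>/pretreatment.vcf
    variants/<pid>/consequences.tsv
    expression/<pid>.tsv         per-gene TPM
    proteins.faa                 shared wild-type proteome
    hla/<pid>.txt                patient HLA class I alleles
    ic50/<pid>.tsv               peptide x allele predicted IC50 table
    elispot/plates.csv           duplicate spot counts
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import neoepitope_pipeline as neo
from . import synthetic_cohort as sc
from .errors import ParameterError
from .response_scoring import LesionMeasurement, SlideAreaRecord
from .variant_consensus import CallerCallSet, ConsensusVariant, VariantKey, normalize_key

_CONTIGS = {f"chr{i}": 250_000_000 for i in range(1, 23)}


def _vcf_header(extra_info=()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in _CONTIGS.items():
        header.contigs.add(name, length=length)
    header.info.add("CALLER", 1, "String", "Name of the emitting variant caller")
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    for args in extra_info:
        header.info.add(*args)
    return header


def write_callset_vcf(path, callset: CallerCallSet) -> None:
    """One caller's calls as minimal VCF 4.2 (CHROM, POS, REF, ALT, INFO)."""
    header = _vcf_header()
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for key in sorted(callset.calls):
            rec = vf.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.filter.add("PASS")
            rec.info["CALLER"] = callset.caller
            vaf = callset.calls[key]
            if not np.isnan(vaf):
                rec.info["VAF"] = float(vaf)
            vf.write(rec)


def read_callset_vcf(path, caller: str, pass_only: bool = True) -> CallerCallSet:
    """Ingest a caller VCF; keys are normalized so the voting rule is exact.

    ``pass_only`` keeps records whose FILTER is PASS or missing; set it
    False to ingest everything.
    """
    calls = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            if pass_only and filters and filters != ["PASS"]:
                continue
            for alt in rec.alts or ():
                key = normalize_key(rec.contig, rec.pos, rec.ref, alt)
                calls[key] = float(rec.info.get("VAF", float("nan")))
    return CallerCallSet(caller, calls)


def write_keys_vcf(path, keys: Sequence[VariantKey], label: str = "truth") -> None:
    """A bare set of variant keys (e.g., the pretreatment sample) as VCF."""
    header = _vcf_header()
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for key in sorted(keys):
            rec = vf.new_record(contig=key.chrom, start=key.pos - 1,
                                alleles=(key.ref, key.alt))
            rec.filter.add("PASS")
            rec.info["CALLER"] = label
            vf.write(rec)


def read_keys_vcf(path) -> set:
    return set(read_callset_vcf(path, "LoFreq", pass_only=False).calls)


def write_consensus_vcf(path, variants: Sequence[ConsensusVariant]) -> None:
    """Consensus variants with INFO/SUPPORT (comma list) and INFO/NSUPPORT."""
    header = _vcf_header(extra_info=[
        ("SUPPORT", 1, "String", "Comma-separated supporting callers"),
        ("NSUPPORT", 1, "Integer", "Number of supporting callers"),
    ])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda v: v.key):
            rec = vf.new_record(contig=v.key.chrom, start=v.key.pos - 1,
                                alleles=(v.key.ref, v.key.alt))
            rec.filter.add("PASS")
            rec.info["SUPPORT"] = ",".join(sorted(v.supporting_callers))
            rec.info["NSUPPORT"] = v.n_support
            if not np.isnan(v.vaf):
                rec.info["VAF"] = float(v.vaf)
            vf.write(rec)


def read_consensus_vcf(path) -> list:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                key = normalize_key(rec.contig, rec.pos, rec.ref, alt)
                out.append(ConsensusVariant(
                    key,
                    frozenset(str(rec.info["SUPPORT"]).split(",")),
                    float(rec.info.get("VAF", float("nan"))),
                ))
    return out


def write_proteins_fasta(path, proteins: dict) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in
               sorted(proteins.items())]
    SeqIO.write(records, str(path), "fasta")


def read_proteins_fasta(path) -> dict:
    with open(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_tpm_tsv(path, tpm: dict) -> None:
    pd.DataFrame(
        {"gene": sorted(tpm), "tpm": [tpm[g] for g in sorted(tpm)]}
    ).to_csv(path, sep="\t", index=False)


def read_tpm_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"], df["tpm"].astype(float)))


_CONSEQUENCE_COLS = ("chrom", "pos", "ref", "alt", "gene", "protein_change",
                     "kind", "position", "ref_aa", "alt_aa", "inserted",
                     "deleted_length", "tail")


def write_consequences_tsv(path, annotations: dict) -> None:
    """VariantKey -> VariantAnnotation map as a flat consequence table."""
    rows = []
    for key in sorted(annotations):
        ann = annotations[key]
        c = ann.consequence
        rows.append({
            "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
            "gene": ann.gene, "protein_change": ann.protein_change,
            "kind": c.kind, "position": c.position, "ref_aa": c.ref_aa,
            "alt_aa": c.alt_aa, "inserted": c.inserted,
            "deleted_length": c.deleted_length, "tail": c.tail,
        })
    pd.DataFrame(rows, columns=_CONSEQUENCE_COLS).to_csv(path, sep="\t", index=False)


def read_consequences_tsv(path) -> dict:
    from .variant_consensus import VariantAnnotation

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tail": str})
    out = {}
    for r in df.itertuples():
        key = VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        cons = neo.ProteinConsequence(
            kind=str(r.kind), position=int(r.position), ref_aa=str(r.ref_aa),
            alt_aa=str(r.alt_aa), inserted=str(r.inserted),
            deleted_length=int(r.deleted_length), tail=str(r.tail),
        )
        out[key] = VariantAnnotation(str(r.gene), str(r.protein_change), cons)
    return out


def write_ic50_tsv(path, rows: Sequence[tuple]) -> None:
    pd.DataFrame(rows, columns=["peptide", "allele", "ic50_nm"]).to_csv(
        path, sep="\t", index=False
    )


def slide_areas_frame(patients) -> pd.DataFrame:
    rows = [
        {"patient_id": s.patient_id, "site": s.site, "block_id": s.block_id,
         "viable_area_mm2": s.viable_area_mm2, "bed_area_mm2": s.bed_area_mm2}
        for p in patients for s in p.slide_areas
    ]
    return pd.DataFrame(rows)


def read_slide_areas_csv(path) -> list:
    df = pd.read_csv(path)
    return [SlideAreaRecord(str(r.patient_id), str(r.site), str(r.block_id),
                            float(r.viable_area_mm2), float(r.bed_area_mm2))
            for r in df.itertuples()]


def lesions_frame(patients) -> pd.DataFrame:
    rows = [
        {"patient_id": m.patient_id, "site": m.site, "timepoint": m.timepoint,
         "length_mm": m.length_mm, "width_mm": m.width_mm,
         "suspicious_flag": m.suspicious_flag}
        for p in patients for m in p.lesions
    ]
    return pd.DataFrame(rows)


def read_lesions_csv(path) -> list:
    df = pd.read_csv(path)
    return [LesionMeasurement(str(r.patient_id), str(r.site), str(r.timepoint),
                              float(r.length_mm), float(r.width_mm),
                              bool(r.suspicious_flag))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# whole-cohort round trip


def _enumerate_predictor_rows(patient, proteins, predictor):
    """Every (peptide, allele, ic50) pair the analysis could query."""
    rows, seen = [], set()
    for v in patient.truth_variants:
        try:
            ctx = neo.build_mutant_context(proteins[v.gene], v.consequence, gene=v.gene)
        except ParameterError:
            continue
        for pep in neo.enumerate_9mers(ctx):
            for allele in patient.hla_alleles:
                if (pep, allele) in seen:
                    continue
                seen.add((pep, allele))
                rows.append((pep, allele, predictor(pep, allele)))
    return rows


def write_cohort(cohort: "sc.CohortDataset", outdir) -> None:
    out = Path(outdir)
    for sub in ("cells", "pathology", "variants", "expression", "hla", "ic50", "elispot"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    manifest = {
        "params": dataclasses.asdict(cohort.params),
        "predictor": {"seed": cohort.predictor.seed,
                      "strong_fraction": cohort.predictor.strong_fraction},
        "patients": [
            {
                "patient_id": p.patient_id,
                "planted_responder": p.planted_responder,
                "ln_status": p.ln_status,
                "recurrence_within_1yr": p.recurrence_within_1yr,
                "hla_alleles": p.hla_alleles,
                "mif_areas": p.mif_areas,
                "synthesized_peptides": p.synthesized_peptides,
                "elispot_assayed": (
                    cohort.elispot_plates is not None
                    and p.patient_id in set(cohort.elispot_plates["patient_id"])
                ),
            }
            for p in cohort.patients
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    write_proteins_fasta(out / "proteins.faa", cohort.proteins)
    slide_areas_frame(cohort.patients).to_csv(out / "pathology" / "slide_areas.csv", index=False)
    lesions_frame(cohort.patients).to_csv(out / "pathology" / "lesions.csv", index=False)
    if cohort.elispot_plates is not None:
        cohort.elispot_plates.to_csv(out / "elispot" / "plates.csv", index=False)

    for p in cohort.patients:
        for tp, cells in (("pre", p.cells_pre), ("post", p.cells_post)):
            df = cells.copy()
            df.insert(0, "timepoint", tp)
            df.insert(0, "patient_id", p.patient_id)
            df.to_csv(out / "cells" / f"{p.patient_id}_{tp}.csv", index=False)
        vdir = out / "variants" / p.patient_id
        vdir.mkdir(parents=True, exist_ok=True)
        for caller, cs in p.snv_callsets.items():
            write_callset_vcf(vdir / f"{caller}.snv.vcf", cs)
        for caller, cs in p.indel_callsets.items():
            write_callset_vcf(vdir / f"{caller}.indel.vcf", cs)
        write_keys_vcf(vdir / "pretreatment.vcf", sorted(p.pretreatment_keys))
        write_consequences_tsv(vdir / "consequences.tsv", p.annotations)
        write_tpm_tsv(out / "expression" / f"{p.patient_id}.tsv", p.tpm)
        (out / "hla" / f"{p.patient_id}.txt").write_text("\n".join(p.hla_alleles) + "\n")
        write_ic50_tsv(
            out / "ic50" / f"{p.patient_id}.tsv",
            _enumerate_predictor_rows(p, cohort.proteins, cohort.predictor),
        )


def load_cohort(indir) -> "sc.CohortDataset":
    """Read a cohort directory back into memory.

    The binding predictor is reconstructed from the manifest (seed and
    strong-binder fraction), which reproduces the per-patient IC50 tables
    exactly.
    """
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    params = _cohort_params_from_dict(manifest["params"])
    predictor = neo.SyntheticBindingPredictor(**manifest["predictor"])
    proteins = read_proteins_fasta(indir / "proteins.faa")
    slide_areas = read_slide_areas_csv(indir / "pathology" / "slide_areas.csv")
    lesions = read_lesions_csv(indir / "pathology" / "lesions.csv")
    plates_path = indir / "elispot" / "plates.csv"
    plates = pd.read_csv(plates_path) if plates_path.exists() else None

    patients = []
    for meta in manifest["patients"]:
        pid = meta["patient_id"]
        cells = {}
        for tp in ("pre", "post"):
            df = pd.read_csv(indir / "cells" / f"{pid}_{tp}.csv")
            cells[tp] = df.drop(columns=["patient_id", "timepoint"])
        vdir = indir / "variants" / pid
        snv_sets = {
            caller: read_callset_vcf(vdir / f"{caller}.snv.vcf", caller)
            for caller in ("LoFreq", "MuSE", "Mutect2", "Strelka2")
        }
        indel_sets = {
            caller: read_callset_vcf(vdir / f"{caller}.indel.vcf", caller)
            for caller in ("LoFreq", "Mutect2", "Strelka2")
        }
        patients.append(sc.PatientData(
            patient_id=pid,
            planted_responder=bool(meta["planted_responder"]),
            cells_pre=cells["pre"],
            cells_post=cells["post"],
            mif_areas=meta["mif_areas"],
            slide_areas=[s for s in slide_areas if s.patient_id == pid],
            ln_status=meta["ln_status"],
            lesions=[m for m in lesions if m.patient_id == pid],
            truth_variants=[],
            pretreatment_keys=read_keys_vcf(vdir / "pretreatment.vcf"),
            snv_callsets=snv_sets,
            indel_callsets=indel_sets,
            annotations=read_consequences_tsv(vdir / "consequences.tsv"),
            tpm=read_tpm_tsv(indir / "expression" / f"{pid}.tsv"),
            hla_alleles=list(meta["hla_alleles"]),
            proteins=proteins,
            synthesized_peptides=list(meta["synthesized_peptides"]),
            recurrence_within_1yr=bool(meta["recurrence_within_1yr"]),
        ))
    return sc.CohortDataset(params, proteins, patients, predictor, plates)


def _slide_params_from_dict(d: dict) -> sc.SlidePatternParams:
    d = dict(d)
    d["intensity_bin_probs"] = tuple(d["intensity_bin_probs"])
    return sc.SlidePatternParams(**d)


def _cohort_params_from_dict(d: dict) -> sc.CohortParams:
    d = dict(d)
    for k in ("responder_pre", "responder_post", "nonresponder_pre", "nonresponder_post"):
        d[k] = _slide_params_from_dict(d[k])
    path = dict(d["pathology"])
    for k in ("responder_ptr_range", "nonresponder_ptr_range"):
        path[k] = tuple(path[k])
    d["pathology"] = sc.PathologyParams(**path)
    var = dict(d["variants"])
    for k in ("protein_length_range", "vaf_beta"):
        var[k] = tuple(var[k])
    d["variants"] = sc.VariantParams(**var)
    d["caller_noise"] = sc.CallerNoiseParams(**d["caller_noise"])
    d["elispot"] = sc.ElispotParams(**d["elispot"])
    return sc.CohortParams(**d)
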