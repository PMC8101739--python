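"""Readers and writers for the pipeline's file formats.

VCF 4.2 is read through cyvcf2; multi-allelic records are split into one
biallelic key per alternate allele and phased genotype separators are
treated as unphased. Pedigrees use the PLINK 6-column PED core
(FID IID PAT MAT SEX PHENO) with optional named extension columns
PROBAND, ONSET_AGE, AGE and CONTROL after the core. Annotation tables,
gene sets, count tables and tier reports are plain tab-delimited text.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    GeneSet,
    GenotypeMatrix,
    PedigreeSet,
    Sample,
    VariantAnnotation,
    VariantKey,
)

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = ["CHROM", "POS", "REF", "ALT", "GENE", "IMPACT", "MAF", "CADD", "RSID"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_field(record, info_key: str, alt_index: int, n_alt: int):
    """INFO value for one alt; comma-separated per-allele values supported."""
    value = record.INFO.get(info_key)
    if value is None:
        return None
    if isinstance(value, tuple):
        return value[alt_index] if alt_index < len(value) else None
    if isinstance(value, str) and "," in value and n_alt > 1:
        parts = value.split(",")
        return parts[alt_index] if alt_index < len(parts) else None
    return value


def read_vcf(path: PathLike) -> tuple[GenotypeMatrix, list[VariantAnnotation]]:
    """Read a VCF 4.2 file into a dosage matrix plus INFO-derived annotations.

    GT values ``./.``, ``0/0``, ``0/1``, ``1/1`` map to MISSING, 0, 1, 2;
    phase separators are ignored. Multi-allelic records are split so that
    each alternate allele gets its own dosage row (total alternate dosage
    at the site is conserved). INFO keys GENE/IMPACT/MAF/CADD populate the
    annotations; absent keys yield absent fields.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # malformed header
        raise ParseError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    annotations: list[VariantAnnotation] = []
    for rec_num, record in enumerate(vcf, start=1):
        gts = record.genotype.array() if record.genotypes is not None else None
        if gts is None or gts.shape[1] != 3:
            raise ParseError(
                f"{path}: record {rec_num} at {record.CHROM}:{record.POS}: "
                f"ploidy != 2"
            )
        alleles = gts[:, :2]  # (n_samples, 2); negative = missing
        n_alt = len(record.ALT)
        for alt_index, alt in enumerate(record.ALT):
            key = VariantKey(record.CHROM, record.POS, record.REF.upper(), alt.upper())
            dosage = (alleles == alt_index + 1).sum(axis=1).astype(np.int8)
            dosage[(alleles < 0).any(axis=1)] = MISSING
            keys.append(key)
            rows.append(dosage)
            maf = _info_field(record, "MAF", alt_index, n_alt)
            cadd = _info_field(record, "CADD", alt_index, n_alt)
            gene = _info_field(record, "GENE", alt_index, n_alt)
            impact = _info_field(record, "IMPACT", alt_index, n_alt)
            rsid = record.ID
            annotations.append(
                VariantAnnotation(
                    key=key,
                    gene=str(gene) if gene is not None else None,
                    impact=str(impact) if impact is not None else None,
                    maf=float(maf) if maf is not None else None,
                    cadd=float(cadd) if cadd is not None else None,
                    rsid=rsid,
                )
            )
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix(variants=keys, samples=samples, dosages=dosages)
    return matrix, annotations


def write_vcf(
    matrix: GenotypeMatrix,
    path: PathLike,
    annotations: Optional[Iterable[VariantAnnotation]] = None,
) -> None:
    """Write a minimal VCF 4.2 with GT calls and GENE/IMPACT/MAF/CADD INFO."""
    ann = {a.key: a for a in annotations} if annotations is not None else {}
    contigs = sorted({v.chrom for v in matrix.variants})
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famseg\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact class">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        order = sorted(range(matrix.n_variants), key=lambda i: matrix.variants[i])
        for i in order:
            key = matrix.variants[i]
            a = ann.get(key)
            info_parts = []
            if a is not None:
                if a.gene is not None:
                    info_parts.append(f"GENE={a.gene}")
                if a.impact is not None:
                    info_parts.append(f"IMPACT={a.impact}")
                if a.maf is not None:
                    info_parts.append(f"MAF={a.maf:.6g}")
                if a.cadd is not None:
                    info_parts.append(f"CADD={a.cadd:.6g}")
            info = ";".join(info_parts) if info_parts else "."
            rsid = a.rsid if a is not None and a.rsid else "."
            gts = "\t".join(gt_text[int(d)] for d in matrix.dosages[i])
            fh.write(
                f"{key.chrom}\t{key.pos}\t{rsid}\t{key.ref}\t{key.alt}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female", "0": "unknown", "-9": "unknown"}
_PHENO = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
PED_CORE = ["FID", "IID", "PAT", "MAT", "SEX", "PHENO"]


def read_ped(path: PathLike) -> PedigreeSet:
    """Read a PLINK-style PED with optional named extension columns.

    A header line (starting with ``#`` or with ``FID`` as first token) may
    name extension columns PROBAND, ONSET_AGE, AGE, CONTROL after the
    6-column core; without a header the file is treated as core-only.
    """
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty PED file")
    header = PED_CORE
    first = lines[0].lstrip("#").split()
    if first[: len(PED_CORE)] == PED_CORE or lines[0].startswith("#"):
        header = first
        lines = lines[1:]
    families: dict[str, list[Sample]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, start=2 if header is not PED_CORE else 1):
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected >=6 PED columns")
        row = dict(zip(header, fields))
        fid, iid = row["FID"], row["IID"]
        if (fid, iid) in seen:
            raise ParseError(f"{path}:{lineno}: duplicate IID {iid!r} within FID {fid!r}")
        seen.add((fid, iid))
        affection = _PHENO.get(row["PHENO"])
        if affection is None:
            raise ParseError(f"{path}:{lineno}: invalid PHENO {row['PHENO']!r}")
        is_proband = row.get("PROBAND", "0") == "1"
        if is_proband and affection != "affected":
            raise ParseError(
                f"{path}:{lineno}: proband flag on non-affected sample {iid!r}"
            )
        onset = row.get("ONSET_AGE", "")
        age = row.get("AGE", "")
        sample = Sample(
            sample_id=iid,
            family_id=fid,
            father_id=None if row["PAT"] == "0" else row["PAT"],
            mother_id=None if row["MAT"] == "0" else row["MAT"],
            sex=_SEX.get(row["SEX"], "unknown"),
            affection=affection,
            is_proband=is_proband,
            is_independent_control=row.get("CONTROL", "0") == "1",
            onset_age=float(onset) if onset not in ("", ".", "-9") else None,
            current_age=float(age) if age not in ("", ".", "-9") else None,
        )
        families.setdefault(fid, []).append(sample)
    return PedigreeSet(families=families)


def write_ped(pedigrees: PedigreeSet, path: PathLike) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    with open(path, "w") as fh:
        fh.write("\t".join(PED_CORE + ["PROBAND", "ONSET_AGE", "AGE", "CONTROL"]) + "\n")
        for fid in sorted(pedigrees.families):
            for m in pedigrees.families[fid]:
                onset = f"{m.onset_age:.1f}" if m.onset_age is not None else "."
                age = f"{m.current_age:.1f}" if m.current_age is not None else "."
                fh.write(
                    "\t".join(
                        [
                            fid,
                            m.sample_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            pheno_code[m.affection],
                            "1" if m.is_proband else "0",
                            onset,
                            age,
                            "1" if m.is_independent_control else "0",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Annotation tables, gene sets, count tables
# ---------------------------------------------------------------------------

def read_annotations(path: PathLike) -> list[VariantAnnotation]:
    """Read a tab-delimited annotation table (CHROM POS REF ALT GENE IMPACT MAF CADD RSID)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "RSID": str})
    missing = [c for c in ANNOTATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    out: list[VariantAnnotation] = []
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))
        gene = getattr(row, "GENE", None)
        impact = getattr(row, "IMPACT", None)
        maf = getattr(row, "MAF", None)
        cadd = getattr(row, "CADD", None)
        rsid = getattr(row, "RSID", None)
        out.append(
            VariantAnnotation(
                key=key,
                gene=None if pd.isna(gene) else str(gene),
                impact=None if pd.isna(impact) else str(impact),
                maf=None if maf is None or (isinstance(maf, float) and math.isnan(maf)) else float(maf),
                cadd=None if cadd is None or (isinstance(cadd, float) and math.isnan(cadd)) else float(cadd),
                rsid=None if rsid is None or pd.isna(rsid) else str(rsid),
            )
        )
    return out


def merge_annotations(
    primary: Iterable[VariantAnnotation], override: Iterable[VariantAnnotation]
) -> list[VariantAnnotation]:
    """Merge VCF-INFO annotations with a side TSV; the side TSV wins per field."""
    merged = {a.key: a for a in primary}
    for a in override:
        base = merged.get(a.key)
        if base is None:
            merged[a.key] = a
            continue
        merged[a.key] = VariantAnnotation(
            key=a.key,
            gene=a.gene if a.gene is not None else base.gene,
            impact=a.impact if a.impact is not None else base.impact,
            maf=a.maf if a.maf is not None else base.maf,
            cadd=a.cadd if a.cadd is not None else base.cadd,
            rsid=a.rsid if a.rsid is not None else base.rsid,
        )
    return list(merged.values())


def write_candidates(
    annotations: Iterable[VariantAnnotation],
    path: PathLike,
    flags: Optional[dict[VariantKey, dict[str, bool]]] = None,
) -> None:
    """Write an annotation table; optional per-variant boolean flag columns."""
    annotations = list(annotations)
    flag_names: list[str] = []
    if flags:
        flag_names = sorted({name for f in flags.values() for name in f})
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS + [f.upper() for f in flag_names]) + "\n")
        for a in sorted(annotations, key=lambda a: a.key):
            cells = [
                a.key.chrom,
                str(a.key.pos),
                a.key.ref,
                a.key.alt,
                a.gene if a.gene is not None else ".",
                a.impact if a.impact is not None else ".",
                f"{a.maf:.8g}" if a.maf is not None else ".",
                f"{a.cadd:.8g}" if a.cadd is not None else ".",
                a.rsid if a.rsid is not None else ".",
            ]
            for name in flag_names:
                cells.append("1" if flags.get(a.key, {}).get(name, False) else "0")
            fh.write("\t".join(cells) + "\n")


def read_candidates(path: PathLike) -> list[VariantAnnotation]:
    """Read back a candidates table written by :func:`write_candidates`."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."])
    out: list[VariantAnnotation] = []
    for row in df.itertuples(index=False):
        out.append(
            VariantAnnotation(
                key=VariantKey(str(row.CHROM), int(row.POS), row.REF, row.ALT),
                gene=row.GENE if isinstance(row.GENE, str) else None,
                impact=row.IMPACT if isinstance(row.IMPACT, str) else None,
                maf=float(row.MAF) if isinstance(row.MAF, str) else None,
                cadd=float(row.CADD) if isinstance(row.CADD, str) else None,
                rsid=row.RSID if isinstance(row.RSID, str) else None,
            )
        )
    return out


def read_gene_set(path: PathLike, name: Optional[str] = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; empty files are an error."""
    genes = {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not genes:
        raise ParseError(f"{path}: empty gene-set file")
    return GeneSet(name=name or Path(path).stem, genes=frozenset(genes))


def read_count_table(path: PathLike) -> list[tuple[str, int, int]]:
    """Read a SOURCE POS NEG count table (one control source per row)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("SOURCE", "POS", "NEG"):
        if col not in df.columns:
            raise ParseError(f"{path}: count table missing column {col}")
    out = []
    for row in df.itertuples(index=False):
        pos, neg = int(row.POS), int(row.NEG)
        if pos < 0 or neg < 0:
            raise ParseError(f"{path}: negative count for source {row.SOURCE!r}")
        out.append((str(row.SOURCE), pos, neg))
    return out


# ---------------------------------------------------------------------------
# Tier report
# ---------------------------------------------------------------------------

def write_tier_report(report, path: PathLike) -> None:
    """Serialize a TierReport as TSV rows (TIER, SCOPE, COUNT, VARIANTS)."""
    with open(path, "w") as fh:
        fh.write("TIER\tSCOPE\tCOUNT\tVARIANTS\n")
        for fid in sorted(report.per_family_candidates):
            states = sorted(report.per_family_candidates[fid])
            text = ",".join(f"{s.key}:{s.state}" for s in states) or "."
            fh.write(f"segregating\t{fid}\t{len(states)}\t{text}\n")
        for fid in sorted(report.after_freq_impact):
            states = sorted(report.after_freq_impact[fid])
            text = ",".join(f"{s.key}:{s.state}" for s in states) or "."
            fh.write(f"freq_impact\t{fid}\t{len(states)}\t{text}\n")
        survivors = sorted(report.after_cross_family)
        fh.write(
            "cross_family\tglobal\t%d\t%s\n"
            % (len(survivors), ",".join(map(str, survivors)) or ".")
        )
        ordered = [str(p.key) for p in report.prioritized]
        fh.write(
            "prioritized\tglobal\t%d\t%s\n" % (len(ordered), ",".join(ordered) or ".")
        )


def read_tier_report_counts(path: PathLike) -> dict[tuple[str, str], int]:
    """Read back (tier, scope) -> count from a tier-report TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"SCOPE": str})
    return {(row.TIER, row.SCOPE): int(row.COUNT) for row in df.itertuples(index=False)}
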