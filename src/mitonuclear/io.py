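"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCFv4.2 (nuclear diploid GT records; mitochondrial
records haploid on contig "chrM"), gene sets as BED3+, everything else
as TSV with a header. All writers round-trip through the readers here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genotype_qc import MISSING, MITO_CONTIGS, SNPRecord

__all__ = ["write_vcf", "read_vcf", "read_bed", "write_tsv", "read_tsv"]


def write_vcf(
    path: str | Path,
    subjects: list[str],
    nuclear: pd.DataFrame,
    mito: pd.DataFrame,
    meta: list[SNPRecord] | None = None,
    nuclear_pos: pd.Series | None = None,
    mito_pos: pd.Series | None = None,
    nuclear_contig: str = "chr1",
) -> None:
    """Write nuclear (diploid GT) and mitochondrial (haploid GT, contig
    chrM) records to an uncompressed VCFv4.2 file.

    Nuclear dosages are emitted as 0/0, 0/1, 1/1 with ``-1`` as ./.;
    mitochondrial carrier codes as haploid 0 or 1.
    """
    by_id = {m.snp_id: m for m in (meta or [])}
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    contigs = {by_id[s].contig if s in by_id else nuclear_contig
               for s in nuclear.columns}
    for c in sorted(contigs):
        header.contigs.add(c, length=500_000_000)
    header.contigs.add("chrM", length=16_569)
    for s in subjects:
        header.add_sample(s)

    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, snp_id in enumerate(nuclear.columns):
            rec_meta = by_id.get(snp_id)
            contig = rec_meta.contig if rec_meta else nuclear_contig
            pos = (rec_meta.position if rec_meta
                   else int(nuclear_pos[snp_id]) if nuclear_pos is not None
                   else 10_000 * (j + 1))
            alleles = rec_meta.alleles if rec_meta else ("A", "G")
            rec = vcf.new_record(contig=contig, start=pos - 1,
                                 alleles=alleles, id=snp_id)
            col = nuclear[snp_id]
            for s in subjects:
                rec.samples[s]["GT"] = gt_codes[int(col[s])]
            vcf.write(rec)
        for j, snp_id in enumerate(mito.columns):
            rec_meta = by_id.get(snp_id)
            pos = (rec_meta.position if rec_meta
                   else int(mito_pos[snp_id]) if mito_pos is not None
                   else 100 * (j + 1))
            alleles = rec_meta.alleles if rec_meta else ("A", "G")
            rec = vcf.new_record(contig="chrM", start=pos - 1,
                                 alleles=alleles, id=snp_id)
            col = mito[snp_id]
            for s in subjects:
                rec.samples[s]["GT"] = (int(col[s]),)
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, list[SNPRecord]]:
    """Read a VCF into (nuclear dosage frame, mito carrier frame, metadata).

    Contigs chrM/MT are treated as mitochondrial: any alt allele marks a
    carrier. Nuclear GT fields become alt-allele dosages with missing
    encoded as -1.
    """
    nuclear_cols: dict[str, np.ndarray] = {}
    mito_cols: dict[str, np.ndarray] = {}
    meta: list[SNPRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        subjects = list(vcf.header.samples)
        for i, rec in enumerate(vcf):
            snp_id = rec.id or f"{rec.contig}:{rec.pos}"
            is_mito = rec.contig in MITO_CONTIGS
            vals = np.empty(len(subjects), dtype=np.int8)
            for k, s in enumerate(subjects):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    vals[k] = MISSING
                else:
                    vals[k] = sum(1 for a in gt if a > 0)
            alts = rec.alts or ("N",)
            meta.append(SNPRecord(snp_id=snp_id, contig=rec.contig,
                                  position=rec.pos,
                                  alleles=(rec.ref, alts[0]),
                                  is_mito=is_mito))
            if is_mito:
                mito_cols[snp_id] = np.clip(vals, MISSING, 1)
            else:
                nuclear_cols[snp_id] = vals
    nuclear = pd.DataFrame(nuclear_cols, index=subjects)
    mito = pd.DataFrame(mito_cols, index=subjects)
    return nuclear, mito, meta


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ intervals (half-open, 0-based) into a DataFrame."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {ln}: {line!r}") from exc
            name = parts[3] if len(parts) > 3 else f"interval{ln}"
            rows.append({"chrom": parts[0], "start": start, "end": end,
                         "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    # '#'-prefixed lines carry provenance (the serialized run config)
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")
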