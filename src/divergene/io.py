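"""Readers and writers for the external formats the pipeline touches.

Genotypes move through three on-disk representations:

* VCF (text, GT plus optional GP genotype-probability field) via cyvcf2;
* PLINK 1 bed/bim/fam (SNP-major 2-bit codes), read and written directly;
* a TSV trio ``<prefix>.genotypes.tsv / .samples.tsv / .variants.tsv`` that
  round-trips every field of a :class:`~divergene.datasets.GenotypeDataset`
  including categorical variables that VCF/PLINK cannot carry.

Genotype codes count the alternate allele (0/1/2, missing -1).  When a
call-probability matrix is available, genotypes below ``call_prob_min`` are
set to missing at read time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    MISSING,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
    GenotypeDataset,
    make_sample_frame,
    make_variant_frame,
)
from .utils import logger

_FLOAT_FORMAT = "%.17g"


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tabular result as UTF-8 TSV with one header row.

    Floats keep 17 significant digits so a read-back reproduces at least 15.
    """
    if table.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str,
    sample_table: str | Path | None = None,
    call_prob_min: float | None = None,
) -> GenotypeDataset:
    """Read genotypes from ``format`` in {plink, vcf, tsv}.

    ``path`` is the file for VCF, the fileset prefix for PLINK/TSV.
    ``sample_table`` optionally attaches phenotype/sex metadata (TSV with a
    ``sample_id`` column) to formats that cannot carry it.  With
    ``call_prob_min`` set and a probability matrix present, low-confidence
    genotypes become missing.
    """
    if format == "vcf":
        dataset = read_vcf(path)
    elif format == "plink":
        dataset = read_plink(path)
    elif format == "tsv":
        dataset = read_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r} (expected plink, vcf or tsv)")
    if sample_table is not None:
        dataset = attach_sample_table(dataset, read_table(sample_table))
    if call_prob_min is not None and dataset.call_prob is not None:
        mask = dataset.call_prob < call_prob_min
        dataset.G = np.where(mask, MISSING, dataset.G)
        if mask.any():
            logger.info("masked %d genotypes below call probability %.2f", mask.sum(), call_prob_min)
    return dataset


def write_genotypes(dataset: GenotypeDataset, path: str | Path, format: str) -> None:
    if format == "vcf":
        write_vcf(dataset, path)
    elif format == "plink":
        write_plink(dataset, path)
    elif format == "tsv":
        write_tsv(dataset, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def attach_sample_table(dataset: GenotypeDataset, table: pd.DataFrame) -> GenotypeDataset:
    if "sample_id" not in table.columns:
        raise ValueError("sample table must have a sample_id column")
    table = table.astype({"sample_id": str}).set_index("sample_id")
    samples = dataset.samples.copy()
    for col in ("sex_reported", "phenotype", "centre"):
        if col in table.columns:
            samples[col] = table[col].reindex(samples["sample_id"]).to_numpy()
    samples["sex_reported"] = samples["sex_reported"].fillna("unknown")
    return GenotypeDataset(samples, dataset.variants, dataset.G, dataset.call_prob)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reader = VCF(str(path))
    sample_ids = list(reader.samples)
    gp_in_header = "GP" in reader.raw_header
    rows, codes, probs = [], [], []
    has_gp = False
    for record in reader:
        if len(record.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {record.CHROM}:{record.POS} not supported; "
                "split the VCF first"
            )
        vid = record.ID if record.ID not in (None, ".") else f"{record.CHROM}:{record.POS}"
        rows.append((vid, record.CHROM, record.POS, record.REF, record.ALT[0]))
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(record.gt_types)
        codes.append(np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING))
        gp = record.format("GP") if gp_in_header else None
        if gp is not None:
            has_gp = True
            probs.append(np.nanmax(np.asarray(gp, dtype=float), axis=1))
        else:
            probs.append(np.ones(len(sample_ids)))
    reader.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    variants = make_variant_frame(
        [r[0] for r in rows],
        chrom=[r[1] for r in rows],
        pos=[r[2] for r in rows],
        ref=[r[3] for r in rows],
        alt=[r[4] for r in rows],
    )
    samples = make_sample_frame(sample_ids)
    G = np.column_stack(codes).astype(np.int8)
    call_prob = np.column_stack(probs) if has_gp else None
    return GenotypeDataset(samples, variants, G, call_prob)


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a minimal single-allelic VCF 4.2 with GT (and GP if present)."""
    if dataset.variants["is_categorical"].any():
        raise ValueError("categorical variables cannot be written to VCF; use the TSV format")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = "GT:GP" if dataset.call_prob is not None else "GT"
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w", encoding="utf-8") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(dataset.variants["chrom"].astype(str)):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dataset.call_prob is not None:
            out.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">\n'
            )
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        for j, var in dataset.variants.iterrows():
            fields = [
                str(var["chrom"]),
                str(int(var["pos"])),
                var["variant_id"],
                str(var["ref"]),
                str(var["alt"]),
                ".",
                ".",
                ".",
                fmt,
            ]
            for i in range(dataset.n_samples):
                cell = gt_strings[int(dataset.G[i, j])]
                if dataset.call_prob is not None:
                    p = dataset.call_prob[i, j]
                    rest = (1.0 - p) / 2.0
                    gp = [rest, rest, rest]
                    code = int(dataset.G[i, j])
                    gp[code if code != MISSING else 0] = p
                    cell += ":" + ",".join(f"{v:.4f}" for v in gp)
                fields.append(cell)
            out.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit code -> alt-allele dosage with A1 = alt: 00 hom-A1, 01 missing, 10 het, 11 hom-A2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_SEX_FROM_FAM = {"1": "male", "2": "female"}
_PHENO_FROM_FAM = {"1": "control", "2": "case"}


def read_plink(prefix: str | Path) -> GenotypeDataset:
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"], dtype=str,
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    samples = make_sample_frame(
        fam_df["iid"],
        sex_reported=[_SEX_FROM_FAM.get(s, "unknown") for s in fam_df["sex"]],
        phenotype=[_PHENO_FROM_FAM.get(p) for p in fam_df["phenotype"]],
    )
    variants = make_variant_frame(
        bim_df["variant_id"],
        chrom=bim_df["chrom"],
        pos=bim_df["pos"].astype(int),
        ref=bim_df["a2"],
        alt=bim_df["a1"],
    )
    n, m = len(samples), len(variants)
    raw = Path(bed).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{bed}: not a SNP-major PLINK .bed file (bad magic bytes)")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise ValueError(f"{bed}: size does not match {n} samples x {m} variants")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, sample index advancing within each byte from LSB
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    G = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]].T.copy()
    return GenotypeDataset(samples, variants, G)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    if dataset.variants["is_categorical"].any():
        raise ValueError("categorical variables cannot be written to PLINK; use the TSV format")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sex_code = {"male": "1", "female": "2"}
    pheno_code = {"control": "1", "case": "2"}
    with open(prefix.with_suffix(".fam"), "w", encoding="utf-8") as out:
        for _, s in dataset.samples.iterrows():
            out.write(
                f"{s['sample_id']} {s['sample_id']} 0 0 "
                f"{sex_code.get(s['sex_reported'], '0')} "
                f"{pheno_code.get(s['phenotype'], '-9')}\n"
            )
    with open(prefix.with_suffix(".bim"), "w", encoding="utf-8") as out:
        for _, v in dataset.variants.iterrows():
            out.write(
                f"{v['chrom']}\t{v['variant_id']}\t0\t{int(v['pos'])}\t{v['alt']}\t{v['ref']}\n"
            )
    n, m = dataset.n_samples, dataset.n_variants
    encode = np.zeros(4, dtype=np.uint8)
    encode[[2, 1, 0]] = [0b00, 0b10, 0b11]  # dosage -> 2-bit code
    codes = np.where(dataset.G == MISSING, 0b01, encode[np.clip(dataset.G, 0, 2)]).astype(np.uint8)
    padded = np.zeros((m, ((n + 3) // 4) * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(m, -1, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as out:
        out.write(_BED_MAGIC)
        out.write(packed.tobytes())


# ---------------------------------------------------------------------------
# TSV trio (full fidelity)
# ---------------------------------------------------------------------------

def read_tsv(prefix: str | Path) -> GenotypeDataset:
    prefix = Path(prefix)
    geno = pd.read_csv(Path(f"{prefix}.genotypes.tsv"), sep="\t", index_col=0)
    samples = pd.read_csv(Path(f"{prefix}.samples.tsv"), sep="\t", dtype={"sample_id": str})
    variants = pd.read_csv(Path(f"{prefix}.variants.tsv"), sep="\t", dtype={"variant_id": str})
    samples = make_sample_frame(
        samples["sample_id"],
        sex_reported=samples.get("sex_reported"),
        phenotype=samples.get("phenotype"),
        centre=samples.get("centre"),
    )
    variants = make_variant_frame(
        variants["variant_id"],
        chrom=variants["chrom"],
        pos=variants["pos"],
        ref=variants.get("ref"),
        alt=variants.get("alt"),
        is_categorical=variants.get("is_categorical"),
    )
    if list(geno.index.astype(str)) != list(samples["sample_id"]):
        raise ValueError("genotype row ids do not match the sample table")
    if list(geno.columns.astype(str)) != list(variants["variant_id"]):
        raise ValueError("genotype column ids do not match the variant table")
    cp_path = Path(f"{prefix}.callprob.tsv")
    call_prob = None
    if cp_path.exists():
        call_prob = pd.read_csv(cp_path, sep="\t", index_col=0).to_numpy(dtype=float)
    return GenotypeDataset(samples, variants, geno.to_numpy(dtype=np.int16), call_prob)


def write_tsv(dataset: GenotypeDataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno = pd.DataFrame(
        dataset.G, index=pd.Index(dataset.sample_ids, name="sample_id"),
        columns=dataset.variant_ids,
    )
    geno.to_csv(Path(f"{prefix}.genotypes.tsv"), sep="\t")
    write_table(dataset.samples[SAMPLE_COLUMNS], Path(f"{prefix}.samples.tsv"))
    write_table(dataset.variants[VARIANT_COLUMNS], Path(f"{prefix}.variants.tsv"))
    if dataset.call_prob is not None:
        pd.DataFrame(
            dataset.call_prob, index=pd.Index(dataset.sample_ids, name="sample_id"),
            columns=dataset.variant_ids,
        ).to_csv(Path(f"{prefix}.callprob.tsv"), sep="\t", float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# gene annotation (BED / GFF3)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read gene intervals into (gene_id, chrom, start, end, strand), 1-based inclusive.

    BED input (0-based half-open) is converted on read; GFF3 rows with
    feature type ``gene`` are used, gene_id taken from ID= or gene_id=.
    """
    import pyranges as pr

    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if format == "bed":
        df = pr.read_bed(str(path)).df
        id_col = "Name"
    elif format == "gff3":
        df = pr.read_gff3(str(path)).df
        df = df[df["Feature"] == "gene"].reset_index(drop=True)
        id_col = next((c for c in ("ID", "gene_id", "Name") if c in df.columns), None)
        if id_col is None or df[id_col].isna().any():
            raise ValueError(f"gene records without an ID attribute in {path}")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    genes = pd.DataFrame(
        {
            "gene_id": df[id_col].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int) + 1,  # pyranges is 0-based half-open
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str) if "Strand" in df.columns else ".",
        }
    )
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicated gene ids in annotation")
    return genes
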