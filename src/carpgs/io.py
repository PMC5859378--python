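"""Readers and writers for the pipeline's standard formats.

Genotypes travel as VCF 4.2 (GT-only, chromosomes ``LG1``..``LG50``,
positions ``round(cM * 1e5)`` so map coordinates survive the integer
requirement) or as a TSV dosage matrix (first column ``id``, header row of
marker names, missing = ``NA``).  Pedigrees and phenotypes are plain CSV.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree

POS_SCALE = 100_000  # cM -> integer VCF coordinate

_LG_NAME = re.compile(r"^LG(\d+)")


def write_vcf(g: GenotypeMatrix, path, extra_header: list[str] | None = None) -> None:
    """Write a GT-only VCF 4.2; one biallelic A/G site per marker."""
    m = g.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=carpgs\n")
        for line in extra_header or []:
            fh.write(f"##{line}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for lg in pd.unique(m["lg"]):
            fh.write(f"##contig=<ID=LG{int(lg)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.samples)) + "\n")
        gt_codes = np.array(["0/0", "0/1", "1/1", "./."])
        codes = g.dosages.copy()
        codes[codes == MISSING] = 3
        for j in range(g.n_loci):
            pos = max(1, int(round(float(m["pos_cm"].iloc[j]) * POS_SCALE)))
            row = "\t".join(gt_codes[codes[:, j]])
            fh.write(f"LG{int(m['lg'].iloc[j])}\t{pos}\t{m['marker'].iloc[j]}"
                     f"\tA\tG\t.\t.\t.\tGT\t{row}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into a dosage matrix.

    Dosage counts the ALT allele; multiallelic sites are skipped with a
    warning.  Sample ids keep file order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    rows, names, lgs, poss = [], [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        rows.append(remap[variant.gt_types])
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        m = _LG_NAME.match(variant.CHROM)
        lgs.append(int(m.group(1)) if m else 0)
        poss.append(variant.POS / POS_SCALE)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic site(s)")
    if not rows:
        raise ValueError(f"no biallelic sites in {path}")
    dosages = np.stack(rows, axis=1)
    markers = pd.DataFrame({"marker": names, "lg": lgs, "pos_cm": poss})
    return GenotypeMatrix(dosages, samples, markers)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages.astype(object), index=pd.Index(g.samples, name="id"),
                      columns=g.markers["marker"])
    df = df.mask(g.dosages == MISSING, "NA")
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    d = df.to_numpy(dtype=float)
    d[np.isnan(d)] = MISSING
    names = df.columns.to_numpy(dtype=object)
    lgs = [int(m.group(1)) if (m := _LG_NAME.match(str(c))) else 0 for c in names]
    markers = pd.DataFrame({"marker": names, "lg": lgs, "pos_cm": 0.0})
    return GenotypeMatrix(d.astype(np.int8), df.index.to_numpy(dtype=object), markers)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on declared format or file suffix ('vcf' or 'tsv')."""
    fmt = format or ("vcf" if str(path).endswith(".vcf") else "tsv")
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id"}
    if not required.issubset(df.columns):
        raise ValueError("phenotype CSV needs an 'id' column")
    return df


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_csv(path)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_csv(path)


def write_table_with_provenance(df: pd.DataFrame, path, seed, config_hash: str) -> None:
    """TSV with a leading comment line recording seed and config hash."""
    with open(path, "w") as fh:
        fh.write(f"# carpgs seed={seed} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
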