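"""Plain-text readers/writers for genotypes, phenotypes and penetrance tables.

Genotypes round-trip through a TSV matrix (individuals x SNPs, header row of
SNP IDs) or a minimal VCF 4.2 export (GT field only, synthetic positions).
Phenotypes are a two-column TSV (individual ID, status) and penetrance tables
a 3x3 CSV with the MAFs in a comment header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gensim import GenotypeMatrix
from .phenosim import PenetranceModel

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_penetrance_csv",
    "read_penetrance_csv",
]


def _snp_ids(p: int):
    return [f"snp{j}" for j in range(p)]


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.values, columns=_snp_ids(G.p))
    with open(path, "w") as fh:
        fh.write("#mafs\t" + "\t".join(f"{q:.10g}" for q in G.mafs) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#mafs\t"):
            raise ValueError("missing #mafs header line")
        mafs = np.array([float(tok) for tok in first.rstrip("\n").split("\t")[1:]])
        df = pd.read_csv(fh, sep="\t")
    return GenotypeMatrix(values=df.to_numpy(dtype=np.int8), mafs=mafs)


def write_genotypes_vcf(G: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Minimal unphased VCF 4.2 (GT only); positions are synthetic 1-based."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    n, p = G.values.shape
    samples = [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epiforest synthetic genotypes\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Simulated MAF">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(p):
            gts = "\t".join(gt_codes[int(g)] for g in G.values[:, j])
            fh.write(
                f"{chrom}\t{j + 1}\tsnp{j}\tA\tG\t.\t.\tMAF={G.mafs[j]:.10g}\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    dosage_of = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2}
    columns: list[list[int]] = []
    mafs: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            mafs.append(float(info["MAF"]))
            columns.append([dosage_of[gt] for gt in fields[9:]])
    values = np.array(columns, dtype=np.int8).T
    return GenotypeMatrix(values=values, mafs=np.array(mafs))


def write_phenotypes_tsv(labels, path) -> None:
    labels = np.asarray(labels)
    pd.DataFrame(
        {"individual": [f"ind{i}" for i in range(labels.size)], "status": labels}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["status"].to_numpy(dtype=np.int8)


def write_penetrance_csv(model: PenetranceModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#mafs,{model.mafs[0]:.10g},{model.mafs[1]:.10g}\n")
        fh.write(f"#loci,{model.locus_a},{model.locus_b}\n")
        pd.DataFrame(model.table, index=[0, 1, 2], columns=[0, 1, 2]).to_csv(fh)


def read_penetrance_csv(path) -> PenetranceModel:
    mafs = loci = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#mafs,"):
            mafs = tuple(float(tok) for tok in line.strip().split(",")[1:])
        elif line.startswith("#loci,"):
            loci = tuple(int(tok) for tok in line.strip().split(",")[1:])
        else:
            body.append(line)
    if mafs is None:
        raise ValueError("missing #mafs header")
    from io import StringIO

    table = pd.read_csv(StringIO("".join(body)), index_col=0).to_numpy(dtype=float)
    kwargs = {}
    if loci is not None:
        kwargs = {"locus_a": loci[0], "locus_b": loci[1]}
    return PenetranceModel(table=table, mafs=mafs, **kwargs)
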