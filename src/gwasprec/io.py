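"""Readers and writers for the standard exchange formats.

Phased haplotype panels round-trip through VCF (GT with the ``|``
separator), so externally simulated or real phased data can replace the
built-in generator; imputed dosages export as VCF with DS/INFO annotations;
phenotypes as two-column TSV; summary tables as TSV/JSON.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotyping import ImputationResult
from .popgen import HaplotypePanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_vcf",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=gwasprec
##contig=<ID=1,length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">
"""


def write_vcf(panel: HaplotypePanel, path, sample_prefix: str = "ind") -> None:
    """Write a phased haplotype panel as uncompressed VCF."""
    n_ind = panel.individual_count
    samples = [f"{sample_prefix}{i}" for i in range(n_ind)]
    a = panel.alleles
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(length=panel.region_length))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for s in range(panel.n_sites):
            gts = "\t".join(f"{a[2 * i, s]}|{a[2 * i + 1, s]}" for i in range(n_ind))
            fh.write(f"1\t{panel.positions[s]}\tv{s}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, region_length: int | None = None) -> HaplotypePanel:
    """Read a phased VCF back into a haplotype panel (biallelic sites,
    phased GT required)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions, rows = [], []
    length = region_length
    if length is None:
        for line in vcf.raw_header.splitlines():
            if line.startswith("##contig") and "length=" in line:
                length = int(line.split("length=")[1].rstrip(">").split(",")[0])
                break
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site at {var.POS} is not biallelic")
        gts = np.asarray(var.genotype.array())
        if not np.all(gts[:, 2] == 1):
            raise ValueError(f"unphased genotype at position {var.POS}")
        positions.append(var.POS)
        rows.append(gts[:, :2].reshape(-1))
    vcf.close()
    alleles = np.asarray(rows, dtype=np.uint8).T
    positions = np.asarray(positions, dtype=np.int64)
    if length is None:
        length = int(positions[-1])
    return HaplotypePanel(positions, alleles, length)


def write_dosage_vcf(result: ImputationResult, path, sample_prefix: str = "ind") -> None:
    """Export imputed dosages as VCF with a DS FORMAT field and the
    INFO-score annotation."""
    n_ind = result.dosages.shape[0]
    samples = [f"{sample_prefix}{i}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=gwasprec-impute\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO score">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped marker site">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Posterior mean dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for s in range(result.positions.size):
            info = f"INFO={result.info[s]:.4f}" + (";TYPED" if result.typed[s] else "")
            ds = "\t".join(f"{d:.3f}" for d in result.dosages[:, s])
            fh.write(f"1\t{result.positions[s]}\tv{result.site_indices[s]}\tA\tG\t.\tPASS\t{info}\tDS\t{ds}\n")


def write_phenotype_tsv(y: np.ndarray, path, sample_prefix: str = "ind") -> None:
    y = np.asarray(getattr(y, "y", y), dtype=float)
    pd.DataFrame(
        {"iid": [f"{sample_prefix}{i}" for i in range(y.size)], "phenotype": y}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotype_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["phenotype"].to_numpy(dtype=float)
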