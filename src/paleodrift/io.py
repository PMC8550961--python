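"""File I/O: EIGENSTRAT trio, VCF 4.2, read-count and metadata TSVs.

Pseudo-haploid calls are written with the derived allele first: a geno
character of ``1`` means the sampled allele is derived, ``0`` ancestral,
``9`` missing.  VCF output encodes calls as haploid genotypes with
REF = ancestral and ALT = derived; heterozygous genotypes on input are a
contract violation for pseudo-haploid panels and raise an error naming
the sample and site.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .panel import MISSING, CallMatrix, ReadCounts, SitePanel

_GENO_CHAR = {0: "0", 1: "1", MISSING: "9"}
_CHAR_GENO = {"0": 0, "1": 1, "9": MISSING}


def write_eigenstrat(calls: CallMatrix, prefix: str, groups=None) -> None:
    """Write ``prefix``.geno/.snp/.ind. One geno line per site, one char per sample."""
    table = calls.sites.table
    with open(prefix + ".geno", "w") as fh:
        for s in range(calls.n_sites):
            fh.write("".join(_GENO_CHAR[int(v)] for v in calls.data[:, s]) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for s in range(calls.n_sites):
            row = table.iloc[s]
            fh.write(
                f"rs{s + 1}\t{row['chrom']}\t0.0\t{int(row['pos'])}"
                f"\t{row['derived']}\t{row['ancestral']}\n"
            )
    groups = groups if groups is not None else ["Unknown"] * calls.n_samples
    with open(prefix + ".ind", "w") as fh:
        for sid, grp in zip(calls.samples, groups):
            fh.write(f"{sid}\tU\t{grp}\n")


def read_eigenstrat(prefix: str) -> tuple[CallMatrix, pd.DataFrame]:
    """Read an EIGENSTRAT trio; returns (CallMatrix, ind table)."""
    ind = pd.read_csv(
        prefix + ".ind", sep=r"\s+", header=None, names=["id", "sex", "group"],
        dtype=str,
    )
    if ind["id"].duplicated().any():
        dup = ind["id"][ind["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicated sample id {dup!r} in {prefix}.ind")
    snp = pd.read_csv(
        prefix + ".snp", sep=r"\s+", header=None,
        names=["id", "chrom", "gpos", "pos", "derived", "ancestral"],
        dtype={"chrom": str},
    )
    sites = SitePanel(
        snp[["chrom", "pos", "ancestral", "derived"]].assign(
            ancestral=snp["ancestral"].astype(str), derived=snp["derived"].astype(str)
        )
    )
    n_samples = len(ind)
    data = np.empty((n_samples, len(snp)), dtype=np.int8)
    with open(prefix + ".geno") as fh:
        for s, line in enumerate(fh):
            line = line.strip()
            if len(line) != n_samples:
                raise ValueError(
                    f"{prefix}.geno line {s + 1} has {len(line)} calls, expected {n_samples}"
                )
            for i, ch in enumerate(line):
                try:
                    data[i, s] = _CHAR_GENO[ch]
                except KeyError:
                    raise ValueError(f"invalid geno character {ch!r} at line {s + 1}")
    if s + 1 != len(snp):
        raise ValueError(f"{prefix}.geno has {s + 1} lines but .snp lists {len(snp)} sites")
    return CallMatrix(data, list(ind["id"]), sites), ind


def write_vcf(calls: CallMatrix, path: str) -> None:
    """Write a plain-text VCF 4.2 with haploid genotypes (REF = ancestral)."""
    table = calls.sites.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in table["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.samples)
            + "\n"
        )
        for s in range(calls.n_sites):
            row = table.iloc[s]
            gts = "\t".join(
                "." if v == MISSING else str(int(v)) for v in calls.data[:, s]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\trs{s + 1}\t{row['ancestral']}"
                f"\t{row['derived']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> CallMatrix:
    """Read a pseudo-haploid VCF (haploid or homozygous-diploid genotypes).

    Heterozygous genotypes raise an error naming the offending sample and
    site.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicated sample ids in VCF header")
    rows = []
    calls_cols = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"site {rec.chrom}:{rec.pos} is not biallelic")
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ancestral": rec.ref,
                "derived": rec.alts[0],
            }
        )
        col = np.empty(len(samples), dtype=np.int8)
        for i, sid in enumerate(samples):
            gt = rec.samples[sid]["GT"]
            alleles = [a for a in gt if a is not None]
            if not alleles:
                col[i] = MISSING
            elif len(set(alleles)) > 1:
                raise ValueError(
                    f"heterozygous genotype for sample {sid!r} at "
                    f"{rec.chrom}:{rec.pos}; pseudo-haploid panels require "
                    "haploid or homozygous calls"
                )
            else:
                col[i] = alleles[0]
        calls_cols.append(col)
    data = np.array(calls_cols, dtype=np.int8).T
    return CallMatrix(data, samples, SitePanel(pd.DataFrame(rows)))


def write_read_counts(reads: ReadCounts, sites: SitePanel, path: str) -> None:
    table = sites.table
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tderived\ttotal\n")
        for i, sid in enumerate(reads.samples):
            for s in range(len(table)):
                fh.write(
                    f"{sid}\t{table.iloc[s]['chrom']}\t{int(table.iloc[s]['pos'])}"
                    f"\t{int(reads.derived[i, s])}\t{int(reads.total[i, s])}\n"
                )


def read_read_counts(path: str, sites: SitePanel) -> ReadCounts:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = list(dict.fromkeys(df["sample"]))
    key = list(zip(sites.table["chrom"].astype(str), sites.table["pos"].astype(int)))
    index = {k: s for s, k in enumerate(key)}
    n, S = len(samples), len(sites)
    der = np.zeros((n, S), dtype=np.int64)
    tot = np.zeros((n, S), dtype=np.int64)
    srow = {sid: i for i, sid in enumerate(samples)}
    for _, row in df.iterrows():
        s = index.get((str(row["chrom"]), int(row["pos"])))
        if s is None:
            raise ValueError(f"read-count site {row['chrom']}:{row['pos']} not in panel")
        i = srow[row["sample"]]
        der[i, s] = row["derived"]
        tot[i, s] = row["total"]
    return ReadCounts(der, tot, samples)


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "group", "age_BP", "lat", "lon"}
    if required - set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta


def write_matrix_tsv(values: np.ndarray, labels: list[str], path: str) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
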