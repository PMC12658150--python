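"""Readers and writers for the standard interchange formats.

Mutations travel as VCF (one record per alternate, INFO fields DATASET and
AFCLASS); gene models, CDS and window tables as TSV with 0-based half-open
coordinates; feature tracks as bedGraph; masks as BED.  VCF positions are
converted between the format's 1-based convention and the package's
0-based one on read/write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .contexts import MUTATION_COLUMNS
from .genome import Genome


def write_vcf(mutations: pd.DataFrame, genome: Genome, path) -> None:
    header = pysam.VariantHeader()
    for chrom in genome.chroms:
        header.contigs.add(chrom, length=genome.length(chrom))
    header.info.add("DATASET", 1, "String", "Source dataset label")
    header.info.add("AFCLASS", 1, "String", "Allele-frequency class")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m in mutations.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = vf.new_record(contig=m.chrom, start=int(m.pos),
                                stop=int(m.pos) + 1, alleles=(m.ref, m.alt))
            rec.info["DATASET"] = str(m.dataset)
            rec.info["AFCLASS"] = str(m.af_class)
            vf.write(rec)


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into the mutation table; multi-allelic records are split
    into one row per alternate."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ds = rec.info.get("DATASET", "unknown")
            af = rec.info.get("AFCLASS", "unknown")
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # SNVs only
                rows.append((rec.contig, rec.start, rec.ref, alt, ds, af))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"] + [c for c in df.columns
                                    if c not in ("chrom", "start", "end")]] \
        .to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return read_bed(path, names=("chrom", "start", "end", "value"))


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(path, sep="\t",
                                                     header=False, index=False)


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_pfm_tsv(path) -> np.ndarray:
    """4 x L position frequency matrix, rows A/C/G/T."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.loc[["A", "C", "G", "T"]].to_numpy(dtype=float)
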