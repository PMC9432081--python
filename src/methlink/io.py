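"""File-format I/O: FASTA genomes, GFF3/BED6 gene annotations, TSV tables.

Conventions: coordinates are 1-based inclusive in memory and in GFF3
output; BED6 output is converted to 0-based half-open at this boundary.
TSV output uses a fixed float format so identical runs produce
byte-identical files.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

FLOAT_FORMAT = "%.6g"


def read_fasta(path) -> dict:
    """Genome as an ordered dict chrom -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genes(path) -> pd.DataFrame:
    """Gene table from GFF3 (gene features) or BED6, by file extension."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path)
    if path.suffix.lower() == ".bed":
        return _read_genes_bed6(path)
    raise ValueError(f"unrecognised annotation extension: {path.suffix}")


def _read_genes_gff3(path) -> pd.DataFrame:
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        row = {"gene_id": feat.id, "chrom": feat.seqid,
               "start": feat.start, "end": feat.end, "strand": feat.strand}
        if "tf_family" in feat.attributes:
            row["tf_family"] = feat.attributes["tf_family"][0]
        rows.append(row)
    return pd.DataFrame(rows)


def _read_genes_bed6(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start0", "end", "gene_id", "score",
                             "strand"])
    return pd.DataFrame({"gene_id": bed["gene_id"], "chrom": bed["chrom"],
                         "start": bed["start0"] + 1, "end": bed["end"],
                         "strand": bed["strand"]})


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            attrs = f"ID={g.gene_id}"
            fam = getattr(g, "tf_family", None)
            if isinstance(fam, str) and fam:
                attrs += f";tf_family={fam}"
            fh.write(f"{g.chrom}\tmethlink\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def write_bed6(genes: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"chrom": genes["chrom"], "start0": genes["start"] - 1,
                        "end": genes["end"], "name": genes["gene_id"],
                        "score": 0, "strand": genes["strand"]})
    out.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic TSV output (fixed float formatting)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
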