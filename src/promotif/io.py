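"""Readers and writers for the pipeline's plain-text interchange formats.

Expression TSV (first column ``gene_id``, remaining columns sample ids),
design TSV (``sample_id<TAB>group``), ortholog TSV
(``gene_id<TAB>ortholog_id_or_NA``), FASTA promoters with ``>geneID|species``
headers, TRANSFAC matrices, BED6 site hits and TSV reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM, PromoterRecord, SiteHit, parse_transfac, write_transfac


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if df.isna().any().any():
        raise ValueError("missing values in expression matrix")
    return df.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_design_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError("design TSV must have columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def write_design_tsv(design: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.keys()), "group": list(design.values())}
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str | Path) -> dict[str, str | None]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["gene_id", "ortholog_id"]:
        raise ValueError("ortholog TSV must have columns gene_id, ortholog_id")
    return {
        g: (None if o == "NA" else o) for g, o in zip(df["gene_id"], df["ortholog_id"])
    }


def write_ortholog_tsv(table: Mapping[str, str | None], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": list(table.keys()),
            "ortholog_id": [o if o is not None else "NA" for o in table.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def read_promoter_fasta(path: str | Path) -> dict[str, PromoterRecord]:
    """Read promoters keyed by gene id; headers are ``geneID|species``."""
    records: dict[str, PromoterRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"FASTA header {rec.id!r} is not 'geneID|species'")
        gene_id, species = rec.id.split("|", 1)
        records[gene_id] = PromoterRecord(
            gene_id=gene_id, species=species, sequence=str(rec.seq)
        )
    return records


def write_promoter_fasta(
    promoters: Sequence[PromoterRecord], path: str | Path
) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=f"{p.gene_id}|{p.species}", description="")
        for p in promoters
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_transfac_file(path: str | Path) -> list[PWM]:
    with open(path) as fh:
        return parse_transfac(fh)


def write_transfac_file(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        write_transfac(pwms, fh)


def write_hits_bed(
    hits: Sequence[SiteHit],
    species: str,
    path: str | Path,
    matrix_lengths: Mapping[str, int] | None = None,
) -> None:
    """BED6: chrom = geneID|species, name = matrix id, score = 1000*MSS."""
    lengths = matrix_lengths or {}
    with open(path, "w") as fh:
        for h in hits:
            end = h.start + lengths.get(h.matrix_id, 1)
            fh.write(
                f"{h.gene_id}|{species}\t{h.start}\t{end}\t"
                f"{h.matrix_id}\t{round(1000 * h.mss)}\t{h.strand}\n"
            )


def write_hits_tsv(hits: Sequence[SiteHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "matrix_id": h.matrix_id,
                "start": h.start,
                "strand": h.strand,
                "mss": h.mss,
                "css": h.css,
            }
            for h in hits
        ],
        columns=["gene_id", "matrix_id", "start", "strand", "mss", "css"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_hits_tsv(path: str | Path) -> list[SiteHit]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "matrix_id": str})
    return [
        SiteHit(
            gene_id=r.gene_id,
            matrix_id=r.matrix_id,
            start=int(r.start),
            strand=r.strand,
            mss=float(r.mss),
            css=float(r.css),
        )
        for r in df.itertuples()
    ]


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
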