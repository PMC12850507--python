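"""Readers and writers for the pipeline's interchange formats.

TSV with a header and optional leading ``#`` provenance comments is the
interchange dialect for tabular data. BED emissions are 0-based
half-open; site tables are 1-based (VCF convention). FASTA is plain
text, wrapped at 70 columns. Expression matrices are read from dense TSV
(cells x genes) or matrix-market triplets. Every writer's output is
re-parseable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_tsv(df: pd.DataFrame, path: str | Path, comments: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(annotation: pd.DataFrame, path: str | Path, feature: str = "utr") -> None:
    """Write gene or 3'UTR intervals as BED6 (0-based half-open)."""
    start, end = (f"{feature}_start", f"{feature}_end") if feature != "gene" else ("gene_start", "gene_end")
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation[start],
            "end": annotation[end],
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 into the package's UTR-annotation frame.

    Gene intervals default to the UTR interval when only a UTR BED is
    available; a matching gene BED can be merged on gene_id afterwards.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        comment="#",
    )
    return pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "gene_start": bed["start"],
            "gene_end": bed["end"],
            "utr_start": bed["start"],
            "utr_end": bed["end"],
        }
    )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def read_expression(matrix_path: str | Path, labels_path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a cells-x-genes expression matrix with per-cell group labels.

    ``matrix_path`` may be dense TSV (first column = cell id) or a
    matrix-market ``.mtx`` file accompanied by ``<stem>.rows.tsv`` (cell
    ids) and ``<stem>.cols.tsv`` (gene ids).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = sparse.csr_matrix(spio.mmread(matrix_path))
        cells = pd.read_csv(matrix_path.with_suffix(".rows.tsv"), header=None)[0]
        genes = pd.read_csv(matrix_path.with_suffix(".cols.tsv"), header=None)[0]
        matrix = pd.DataFrame(mat.toarray(), index=cells, columns=genes)
    else:
        matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    labels_df = read_tsv(labels_path)
    labels = labels_df.set_index(labels_df.columns[0])[labels_df.columns[1]]
    return matrix, labels.loc[matrix.index]


def write_expression_mtx(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    spio.mmwrite(str(path.with_suffix("")), sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index).to_csv(path.with_suffix(".rows.tsv"), index=False, header=False)
    pd.Series(matrix.columns).to_csv(path.with_suffix(".cols.tsv"), index=False, header=False)


def read_minimal_vcf(path: str | Path) -> pd.DataFrame:
    """Read the minimal VCF dialect (CHROM POS ID REF ALT + per-sample k:n).

    The header line ``#CHROM ...`` carries sample names; an ``INFO``-style
    column is not used. Strand and group must be supplied separately or
    via ``##SAMPLE=<ID=...,Group=...>`` and ``STRAND=`` INFO entries; this
    reader accepts a ``STRAND`` INFO key and ``##SAMPLE`` group lines.
    """
    samples: list[str] = []
    groups: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##SAMPLE=<"):
                body = line[len("##SAMPLE=<") : -1]
                fields = dict(kv.split("=", 1) for kv in body.split(","))
                groups[fields["ID"]] = fields["Group"]
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[8:]
                continue
            if line.startswith("#") or not line:
                continue
            parts = line.split("\t")
            chrom, pos, _id, ref, alt, _qual, _filt, info = parts[:8]
            strand = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv).get("STRAND", "+")
            for sample, cell in zip(samples, parts[8:]):
                k, n = cell.split(":")
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(pos),
                        "strand": strand,
                        "ref": ref,
                        "alt": alt,
                        "sample": sample,
                        "group": groups.get(sample, "treatment"),
                        "k": int(k),
                        "n": int(n),
                    }
                )
    return pd.DataFrame(rows)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
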