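"""Plain-text readers/writers for the pipeline's tabular and JSON formats.

All tables are TSV; pathway maps are JSON. Footprint alignments are read
either from a three-column TSV (``transcript_id``, ``three_prime_pos``,
``read_length``) or from a SAM/BAM file aligned against a padded-transcript
reference, where the 3' end is the last aligned base on the forward strand
(reverse-strand alignments are rejected for transcriptome mappings).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pathways import PathwayMap
from .quantify import CountMatrix, validate_fold_change_table

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_fold_change_table",
    "read_fold_change_table",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "read_alignments_bam",
    "write_pathway_map",
    "read_pathway_map",
    "write_spikein_design",
    "read_spikein_design",
    "read_cell_geometry",
]


def write_count_matrix(cm: CountMatrix, counts_path, metadata_path) -> None:
    table = cm.counts.copy()
    table.insert(0, "length", cm.lengths)
    table.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    table = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    lengths = table.pop("length")
    return CountMatrix(table, lengths, samples)


def write_fold_change_table(fc: pd.DataFrame, path) -> None:
    validate_fold_change_table(fc).to_csv(path, sep="\t", index=False)


def read_fold_change_table(path) -> pd.DataFrame:
    fc = pd.read_csv(path, sep="\t")
    return validate_fold_change_table(fc)


def write_alignments_tsv(reads: pd.DataFrame, path) -> None:
    reads[["transcript_id", "three_prime_pos", "read_length"]].to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "three_prime_pos", "read_length"} - set(reads.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return reads


def read_alignments_bam(path) -> pd.DataFrame:
    """3'-end positions from SAM/BAM alignments to a padded transcriptome.

    The 3' end is the 1-based position of the last aligned base
    (``reference_end`` in pysam's half-open convention). Reverse-strand
    alignments would put the biological 3' end at the alignment start and
    indicate a mis-stranded transcriptome mapping, so they are rejected.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                raise ValueError(
                    f"reverse-strand alignment for read {aln.query_name}; "
                    "transcriptome mappings must be forward-strand"
                )
            rows.append(
                {
                    "transcript_id": aln.reference_name,
                    "three_prime_pos": aln.reference_end,  # half-open end == 1-based last base
                    "read_length": aln.query_length,
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "three_prime_pos", "read_length"])


def write_pathway_map(pmap: PathwayMap, path) -> None:
    Path(path).write_text(json.dumps(pmap.to_dict(), indent=1))


def read_pathway_map(path) -> PathwayMap:
    return PathwayMap.from_dict(json.loads(Path(path).read_text()))


def write_spikein_design(design: pd.DataFrame, path) -> None:
    design[["spikein_id", "sample_id", "molecules"]].to_csv(path, sep="\t", index=False)


def read_spikein_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    if (design["molecules"] <= 0).any():
        raise ValueError("spike-in molecule counts must be positive")
    return design


def read_cell_geometry(path) -> pd.DataFrame:
    geo = pd.read_csv(path, sep="\t")
    missing = {"line", "length_um", "width_um"} - set(geo.columns)
    if missing:
        raise ValueError(f"cell geometry TSV missing columns: {sorted(missing)}")
    return geo
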