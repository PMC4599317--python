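"""Plain-text readers/writers for the pipeline's table formats.

Matrices are TSV with samples as rows. Interval files follow BED
conventions: 0-based half-open coordinates, no header. Probe/SNP manifests
carry 1-based positions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import DomainError

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BED4_COLUMNS = ["chrom", "start", "end", "name"]
BED3_COLUMNS = ["chrom", "start", "end"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = True, na_rep: str = "NA") -> str:
    df.to_csv(path, sep="\t", index=index, na_rep=na_rep, float_format=FLOAT_FORMAT)
    return str(path)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Samples x features matrix with the first column as sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_bed(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False, header=False)
    return str(path)


def read_bed(path, columns=None) -> pd.DataFrame:
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    if columns is None:
        columns = {3: BED3_COLUMNS, 4: BED4_COLUMNS, 6: BED6_COLUMNS}.get(first.shape[1])
        if columns is None:
            columns = BED6_COLUMNS[: first.shape[1]]
    df = pd.read_csv(path, sep="\t", header=None, names=columns)
    bad = df[df["end"] <= df["start"]]
    if len(bad):
        raise DomainError(
            f"{path}: malformed interval (end <= start) at line(s) {list(bad.index + 1)}"
        )
    return df


def write_bedpe(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False, header=False)
    return str(path)


def read_bedpe(path) -> pd.DataFrame:
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    names = BEDPE_COLUMNS[: first.shape[1]]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    for side in ("1", "2"):
        bad = df[df[f"end{side}"] <= df[f"start{side}"]]
        if len(bad):
            raise DomainError(
                f"{path}: malformed anchor pair (end <= start) at line(s) "
                f"{list(bad.index + 1)}"
            )
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
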