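"""Readers and writers for the flat-file formats the pipeline exchanges.

Expression matrices travel as GCT-like TSV (a header row of sample ids after
two leading columns for feature id and description); gene signatures as GMT
with ``<name>_HIGH`` / ``<name>_LOW`` (or ``_UP`` / ``_DOWN``) set pairs;
tabular results as plain TSV/CSV via pandas.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

GCT_VERSION = "#1.2"


def write_gct(expr: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as GCT 1.2.

    The description column is filled with the feature id (the pipeline does
    not carry separate annotations).
    """
    with open(path, "w") as fh:
        fh.write(f"{GCT_VERSION}\n{expr.shape[0]}\t{expr.shape[1]}\n")
        out = expr.copy()
        out.insert(0, "Description", expr.index)
        out.insert(0, "Name", expr.index)
        out.to_csv(fh, sep="\t", index=False)


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 file into a features x samples DataFrame."""
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValidationError(f"not a GCT file (version line {version!r})")
        n_feat, n_samp = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_feat, n_samp):
        raise ValidationError(
            f"GCT header declares {n_feat}x{n_samp} but body is {df.shape[0]}x{df.shape[1]}"
        )
    df.index.name = "feature"
    return df


def write_gmt(sets: dict[str, list[str]], path) -> None:
    """Write named gene sets as GMT (name, description, members...)."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
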