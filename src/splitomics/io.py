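"""Readers and writers for the pipeline's plain-text formats.

Expression and metadata are TSV, gene sets are GMT, networks are
SIF-like three-column TSV (source, sign, target) and spectra are CSV
with the ppm axis as the header row.  All files are UTF-8 with '.' as
the decimal separator; gene identifiers are case-sensitive opaque
strings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import Spectra
from .enrichment import GeneSetCollection
from .network import SIGNS, build_network

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_sif",
    "write_sif",
    "read_spectra",
    "write_spectra",
]


def read_expression(path, metadata_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genes x samples log2 TSV plus a sample -> group TSV.

    The expression file has a header row of sample ids and gene ids in
    the first column; the metadata file has columns ``sample`` and
    ``group``.
    """
    try:
        expr = pd.read_csv(path, sep="\t", index_col=0)
        expr = expr.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed numeric cell in {path}: {exc}") from exc
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup[:5]}")
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample", "group"} <= set(meta.columns):
        raise ValueError(f"{metadata_path} must have 'sample' and 'group' columns")
    groups = pd.Series(meta["group"].values, index=meta["sample"].astype(str))
    missing = [s for s in expr.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return expr, groups.loc[expr.columns]


def write_expression(expr: pd.DataFrame, groups: pd.Series, path, metadata_path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        metadata_path, sep="\t", index=False
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated members."""
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 fields")
            term, name, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no members")
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = frozenset(members)
            names[term] = name
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.sets):
            members = "\t".join(sorted(collection[term]))
            fh.write(f"{term}\t{collection.name(term)}\t{members}\n")


def read_sif(path):
    """Read a SIF-like edge list: ``source<TAB>sign<TAB>target``."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            source, sign, target = fields
            if sign not in SIGNS:
                raise ValueError(
                    f"{path}:{lineno}: unknown sign {sign!r}; expected one of {SIGNS}"
                )
            if source == target:
                raise ValueError(f"{path}:{lineno}: self-loop on {source!r}")
            edges.append((source, sign, target))
    return build_network(edges)


def write_sif(net, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for source, target, data in sorted(net.edges(data=True)):
            fh.write(f"{source}\t{data['sign']}\t{target}\n")


def read_spectra(path, labels_path=None, allow_ascending: bool = False) -> Spectra:
    """Read a spectra CSV (header row = descending ppm axis) and labels TSV.

    An ascending ppm axis is rejected by default (descending is the
    plotting convention); ``allow_ascending`` reverses it in place.
    """
    frame = pd.read_csv(path, index_col=0)
    try:
        ppm = frame.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: header row must be a numeric ppm axis") from exc
    values = frame.apply(pd.to_numeric)
    diffs = np.diff(ppm)
    if ppm.size >= 2 and np.all(diffs > 0):
        if not allow_ascending:
            raise ValueError(
                f"{path}: ppm axis ascends; pass allow_ascending=True to reverse"
            )
        ppm = ppm[::-1]
        values = values.iloc[:, ::-1]
    elif ppm.size >= 2 and not np.all(diffs < 0):
        raise ValueError(f"{path}: ppm axis must be strictly monotone")
    labels = None
    if labels_path is not None:
        meta = pd.read_csv(labels_path, sep="\t")
        if not {"sample", "group"} <= set(meta.columns):
            raise ValueError(f"{labels_path} must have 'sample' and 'group' columns")
        labels = pd.Series(meta["group"].values, index=meta["sample"].astype(str))
    values.columns = range(values.shape[1])
    return Spectra(ppm, values, labels)


def write_spectra(spectra: Spectra, path, labels_path=None) -> None:
    frame = spectra.intensities.copy()
    frame.columns = spectra.ppm
    frame.to_csv(path, index_label="sample")
    if labels_path is not None and spectra.labels is not None:
        pd.DataFrame(
            {"sample": spectra.labels.index, "group": spectra.labels.values}
        ).to_csv(labels_path, sep="\t", index=False)
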