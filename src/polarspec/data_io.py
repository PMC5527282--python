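"""Readers and writers for the expression / gene-set / survival formats.

Conventions
-----------
* An expression matrix is a :class:`pandas.DataFrame` of RMA-scale (log2,
  background-corrected, quantile-normalized) intensities with gene
  identifiers on the index and sample identifiers on the columns.  All
  values must be finite; duplicate gene rows are collapsed on read.
* A ranked list is a :class:`pandas.Series` (index = gene ids, values =
  real scores) sorted descending with lexicographic tie-break on the id.
* Gene-id matching throughout the package is case-insensitive (uppercase
  symbol equality) with original case preserved on output.  This is the
  documented proxy for mouse-symbol -> human-symbol mapping; full ortholog
  mapping is out of scope.

Supported formats: GCT 1.2, plain TSV matrices, GMT gene sets, RNK ranked
lists, two-class CLS phenotype labels, and sample/time/event survival
tables (TSV or CSV).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Structural problem in an input file (bad header, dimension mismatch...)."""


class ValidationError(ValueError):
    """Well-formed file carrying values that violate a type invariant."""


@dataclass
class GeneSet:
    """A named collection of unique gene identifiers (one GMT line)."""

    name: str
    description: str = ""
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        seen: set[str] = set()
        deduped = []
        for m in self.members:
            if m.upper() not in seen:
                seen.add(m.upper())
                deduped.append(m)
        self.members = tuple(deduped)

    def __len__(self) -> int:
        return len(self.members)

    def upper_members(self) -> frozenset[str]:
        return frozenset(m.upper() for m in self.members)


@dataclass
class SurvivalCohort:
    """Per-sample follow-up time and event flag, optionally with expression.

    ``event`` is 1 when death (or the terminal event) was observed and 0
    when the sample was censored.  When ``expression`` is present its
    columns match ``sample_ids`` exactly, in order.
    """

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_ids) != self.time.size or self.time.size != self.event.size:
            raise ValidationError("sample_ids, time and event lengths differ")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise ValidationError("survival times must be finite and non-negative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValidationError("event flags must be 0 (censored) or 1 (event)")
        if self.expression is not None:
            if tuple(self.expression.columns) != tuple(self.sample_ids):
                raise ValidationError("expression columns do not match sample_ids")

    @property
    def n(self) -> int:
        return self.time.size


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene id, the row with the highest mean.

    This is the collapse convention of the GSEA ecosystem ("max_probe"):
    among probes mapping to one symbol, the brightest probe wins.
    Duplicate detection is case-insensitive.
    """
    upper = df.index.str.upper()
    if not upper.duplicated().any():
        return df
    means = df.mean(axis=1).to_numpy()
    order = np.lexsort((-means, upper))
    keep = ~pd.Index(upper[order]).duplicated()
    kept = df.iloc[order[keep]]
    # restore original file order of the surviving rows
    kept = kept.loc[df.index[df.index.isin(kept.index)].drop_duplicates()]
    n_dropped = len(df) - len(kept)
    logger.info("collapsed %d duplicate gene rows (highest-mean rule)", n_dropped)
    return kept


def _validate_expression(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.empty:
        raise FormatError(f"{source}: empty expression matrix")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = df.map(lambda v: isinstance(v, str))
        rows, cols = np.nonzero(bad.to_numpy())
        ctx = ""
        if rows.size:
            ctx = f" (first at gene {df.index[rows[0]]!r}, sample {df.columns[cols[0]]!r})"
        raise FormatError(f"{source}: non-numeric expression value{ctx}") from exc
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{source}: non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if df.columns.duplicated().any():
        raise FormatError(f"{source}: duplicate sample ids")
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return _collapse_duplicate_genes(df)


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a gene x sample expression matrix from GCT 1.2 or plain TSV.

    Parameters
    ----------
    path
        Input file.  Format is inferred from the suffix when ``format`` is
        None (``.gct`` -> GCT, else TSV with gene ids in the first column).
    format
        ``"gct"`` or ``"tsv"`` to force a format.

    Returns
    -------
    pandas.DataFrame
        Finite float matrix, duplicate gene rows collapsed to the
        highest-mean row.
    """
    path = Path(path)
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    if fmt == "gct":
        return _read_gct(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return _validate_expression(df, str(path))
    raise ValueError(f"unknown expression format {fmt!r}")


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = (int(d) for d in dims)
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise FormatError(
            f"{path}: GCT declares {n_rows} rows x {n_cols} samples "
            f"but contains {body.shape[0]} x {body.shape[1] - 2}"
        )
    body = body.set_index(body.columns[0]).drop(columns=body.columns[1])
    return _validate_expression(body, str(path))


def write_gct(expr: pd.DataFrame, path: str | Path, descriptions: Sequence[str] | None = None) -> None:
    """Write an expression matrix as GCT 1.2."""
    path = Path(path)
    desc = list(descriptions) if descriptions is not None else ["na"] * len(expr)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
        for (gene, row), d in zip(expr.iterrows(), desc):
            fh.write(gene + "\t" + d + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def sort_ranked(scores: pd.Series) -> pd.Series:
    """Sort a gene -> score series descending, ties broken by gene id.

    The result is the package-wide RankedList representation.  Ids must be
    unique; scores must be finite.
    """
    if scores.index.duplicated().any():
        raise ValidationError("ranked list has duplicate gene ids")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValidationError("ranked list scores must be finite")
    order = np.lexsort((scores.index.to_numpy(), -scores.to_numpy(dtype=float)))
    out = scores.iloc[order].astype(float)
    out.index = out.index.astype(str)
    out.index.name = None
    out.name = None
    return out


def write_ranked_list(ranked: pd.Series, path: str | Path) -> None:
    """Write a ranked list as a two-column, headerless RNK file.

    The list is (re-)sorted descending with the lexicographic tie rule so
    the written order is canonical; floats are written shortest-repr so a
    read-back reproduces the list exactly.
    """
    ranked = sort_ranked(ranked)
    with open(path, "w") as fh:
        for gene, score in ranked.items():
            fh.write(f"{gene}\t{score!r}\n")


def read_ranked_list(path: str | Path) -> pd.Series:
    """Read an RNK file into the canonical sorted Series form."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], dtype={0: str})
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in RNK file")
    return sort_ranked(pd.Series(df["score"].to_numpy(dtype=float), index=df["gene"]))


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, name / description / members."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
            members = tuple(m for m in fields[2:] if m)
            uniq = len({m.upper() for m in members})
            if uniq < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {fields[0]!r} has duplicate members; deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join((s.name, s.description or "na", *s.members)) + "\n")


_EVENT_TOKENS = {
    "1": 1, "0": 0,
    "true": 1, "false": 0,
    "dead": 1, "deceased": 1, "alive": 0,
    "event": 1, "censored": 0,
}


def read_survival_table(path: str | Path) -> SurvivalCohort:
    """Read a sample/time/event table (TSV or CSV; header optional).

    Event coercion: ``1/0``, ``TRUE/FALSE``, ``dead/deceased/alive``,
    ``event/censored`` (case-insensitive).  1 means the event was observed,
    0 censored.  Negative times are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: survival table needs sample, time, event columns")
    first = df.iloc[0]
    try:
        float(first.iloc[1])
    except ValueError:  # header row
        df = df.iloc[1:]
    samples = df.iloc[:, 0].astype(str).tolist()
    try:
        times = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric time value") from exc
    if np.any(times < 0):
        bad = samples[int(np.argmax(times < 0))]
        raise ValidationError(f"{path}: negative time for sample {bad!r}")
    events = []
    for s, tok in zip(samples, df.iloc[:, 2].astype(str)):
        key = tok.strip().lower()
        if key not in _EVENT_TOKENS:
            raise FormatError(f"{path}: unknown event token {tok!r} for sample {s!r}")
        events.append(_EVENT_TOKENS[key])
    return SurvivalCohort(tuple(samples), times, np.array(events))


def write_survival_table(cohort: SurvivalCohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttime\tevent\n")
        for s, t, e in zip(cohort.sample_ids, cohort.time, cohort.event):
            fh.write(f"{s}\t{float(t)!r}\t{int(e)}\n")


def read_phenotype_labels(path: str | Path) -> list[str]:
    """Read a two-class CLS file into a positional label list.

    CLS dialect: line 1 = ``<n_samples> <n_classes> 1``, line 2 =
    ``# <name1> <name2>``, line 3 = space-separated labels (class names or
    0/1 indices).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS file needs 3 lines")
    counts = lines[0].split()
    if len(counts) != 3:
        raise FormatError(f"{path}: malformed CLS count line {lines[0]!r}")
    n_samples, n_classes = int(counts[0]), int(counts[1])
    if n_classes != 2:
        raise FormatError(f"{path}: only two-class CLS is supported, got {n_classes} classes")
    names = lines[1].lstrip("#").split()
    if len(names) != 2:
        raise FormatError(f"{path}: CLS class-name line must name 2 classes")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(f"{path}: CLS declares {n_samples} labels but has {len(tokens)}")
    labels = []
    for tok in tokens:
        if tok in names:
            labels.append(tok)
        elif tok in ("0", "1"):
            labels.append(names[int(tok)])
        else:
            raise FormatError(f"{path}: CLS label {tok!r} matches neither class name nor 0/1")
    return labels


def write_phenotype_labels(labels: Sequence[str], path: str | Path) -> None:
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValidationError(f"need exactly two classes, got {names}")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(labels) + "\n")


def match_genes(expr_genes: pd.Index | Sequence[str], query: Iterable[str]) -> list[str]:
    """Case-insensitively map query symbols onto matrix gene ids.

    Returns the matrix's own identifiers (original case) for every query
    symbol found, in query order, without duplicates.
    """
    lookup: dict[str, str] = {}
    for g in expr_genes:
        lookup.setdefault(str(g).upper(), str(g))
    out, seen = [], set()
    for q in query:
        hit = lookup.get(str(q).upper())
        if hit is not None and hit not in seen:
            seen.add(hit)
            out.append(hit)
    return out
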