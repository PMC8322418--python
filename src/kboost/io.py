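"""Readers and writers for the plain-text interchange formats.

Expression matrices are delimited text (TSV, or CSV when the extension is
``.csv``) with one header row of sample ids and one id column of gene ids;
a flag transposes genes-in-columns files on input.  Gold standards and
priors use the DREAM-style edge-list convention ``TF <tab> target <tab>
value``; TF lists are one identifier per line.  Inferred networks are
exported as ranked edge lists sorted by score descending with (TF, target)
lexicographic tie-breaks.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import GoldStandard
from .exceptions import FormatError
from .grn_inference import GRNPosterior, PriorMatrix
from .kernel_features import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_tf_list",
    "write_tf_list",
    "read_edge_list",
    "write_gold_standard",
    "read_ranked_edges",
    "write_ranked_edges",
    "write_posterior_matrix",
]

logger = logging.getLogger("kboost")


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a delimited expression matrix.

    ``orientation='genes-in-columns'`` transposes the file, so a file of
    shape samples x genes still yields a genes x samples matrix.
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise FormatError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=_sep(path), index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: expression file has no data cells")
    if orientation == "genes-in-columns":
        df = df.T
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or df[col].isna().any():
            where = bad[0] if bad else df.index[df[col].isna()][0]
            raise FormatError(
                f"{path}: non-numeric or missing value at gene {where!r}, "
                f"sample {col!r}"
            )
        df[col] = coerced
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
    )


def write_expression(X: ExpressionMatrix, path, orientation: str = "genes-in-rows") -> None:
    path = Path(path)
    df = pd.DataFrame(X.values, index=list(X.gene_ids), columns=list(X.sample_ids))
    if orientation == "genes-in-columns":
        df = df.T
    df.to_csv(path, sep=_sep(path))


def read_tf_list(path) -> list[str]:
    """One TF identifier per line; blank lines ignored; duplicates rejected."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise FormatError(f"{path}: empty TF list")
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate TF ids")
    return ids


def write_tf_list(tf_ids, path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in tf_ids))


def _parse_edge_lines(path: Path):
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
        tf, target = parts[0].strip(), parts[1].strip()
        if tf == target:
            raise FormatError(f"{path}:{lineno}: self-loop {tf!r} -> {target!r}")
        value = parts[2].strip() if len(parts) == 3 else None
        yield lineno, tf, target, value


def read_edge_list(
    path,
    mode: str,
    gene_ids: tuple[str, ...],
    tf_ids: list[str] | None = None,
    default_weight: float = 0.5,
    assume_complete: bool = False,
):
    """Read a DREAM-style edge list as a gold standard or a prior matrix.

    gold mode
        Returns a :class:`GoldStandard` keyed by gene-id pairs.  A missing
        third column means label 1.  Pairs absent from the file are
        unlabeled (partial gold) unless ``assume_complete`` is set, in which
        case every unlisted TF x gene pair gets label 0 (requires
        ``tf_ids``).
    prior mode
        Returns a :class:`PriorMatrix` over ``gene_ids`` x ``tf_ids``
        (required), filled with ``default_weight`` and overwritten by the
        listed weights, which must lie strictly in (0, 1).

    Unknown gene identifiers are skipped with a logged warning.
    """
    path = Path(path)
    if mode not in ("gold", "prior"):
        raise FormatError(f"unknown edge-list mode {mode!r}")
    known = set(gene_ids)
    skipped = 0
    if mode == "gold":
        labels: dict[tuple[str, str], int] = {}
        for lineno, tf, target, value in _parse_edge_lines(path):
            if tf not in known or target not in known:
                skipped += 1
                continue
            if value is None:
                lab = 1
            else:
                try:
                    fval = float(value)
                except ValueError:
                    fval = np.nan
                if fval not in (0.0, 1.0):
                    raise FormatError(
                        f"{path}:{lineno}: gold label must be 0 or 1, got {value!r}"
                    )
                lab = int(fval)
            labels[(tf, target)] = lab
        if skipped:
            logger.warning("%s: skipped %d lines with unknown gene ids", path, skipped)
        if not labels:
            raise FormatError(f"{path}: no usable edges")
        if assume_complete:
            if tf_ids is None:
                raise FormatError("assume_complete requires tf_ids")
            for tf in tf_ids:
                for target in gene_ids:
                    if tf != target:
                        labels.setdefault((tf, target), 0)
        return GoldStandard(labels)

    if tf_ids is None:
        raise FormatError("prior mode requires tf_ids")
    row_of = {g: i for i, g in enumerate(gene_ids)}
    col_of = {t: i for i, t in enumerate(tf_ids)}
    weights = np.full((len(gene_ids), len(tf_ids)), float(default_weight))
    for lineno, tf, target, value in _parse_edge_lines(path):
        if tf not in col_of or target not in row_of:
            skipped += 1
            continue
        if value is None:
            raise FormatError(f"{path}:{lineno}: prior lines need a weight column")
        try:
            w = float(value)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric weight {value!r}") from None
        if not (0.0 < w < 1.0):
            raise FormatError(
                f"{path}:{lineno}: prior weight must be in (0, 1), got {value}"
            )
        weights[row_of[target], col_of[tf]] = w
    if skipped:
        logger.warning("%s: skipped %d lines with unknown gene ids", path, skipped)
    return PriorMatrix(weights)


def write_gold_standard(gold: GoldStandard, path) -> None:
    """Write the complete labeled universe as a 3-column TSV (ids as given)."""
    with open(path, "w") as fh:
        for (tf, target) in sorted(gold.labels, key=lambda pair: (str(pair[0]), str(pair[1]))):
            fh.write(f"{tf}\t{target}\t{gold.labels[(tf, target)]}\n")


def read_ranked_edges(path) -> dict[tuple[str, str], float]:
    """Read a ranked edge list back into a {(TF id, target id): score} map."""
    path = Path(path)
    scores: dict[tuple[str, str], float] = {}
    for lineno, tf, target, value in _parse_edge_lines(path):
        if value is None:
            raise FormatError(f"{path}:{lineno}: ranked edge lists need a score column")
        try:
            scores[(tf, target)] = float(value)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric score {value!r}") from None
    if not scores:
        raise FormatError(f"{path}: no edges")
    return scores


def write_ranked_edges(scores: dict[tuple[str, str], float], path) -> None:
    """Write scores sorted descending, ties by (TF, target) lexicographic."""
    rows = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    with open(path, "w") as fh:
        for (tf, target), score in rows:
            if not np.isfinite(score) or score < 0:
                raise FormatError(
                    f"edge ({tf}, {target}) has invalid score {score}"
                )
            fh.write(f"{tf}\t{target}\t{score:.12g}\n")


def write_posterior_matrix(post: GRNPosterior, path, use_scaled: bool = False) -> None:
    """Write the G x P posterior matrix as TSV (rows genes, columns TFs)."""
    mat = post.scaled if use_scaled else post.raw
    df = pd.DataFrame(mat, index=list(post.gene_ids), columns=list(post.tf_ids))
    df.to_csv(path, sep="\t", float_format="%.12g")
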