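"""Reading expression matrices, serializing fitted rules, writing results.

Expression input is plain TSV/CSV (genes as rows, first column the gene
identifier, specimens as columns), either as two per-class files or as one
combined matrix plus a specimen-to-class assignment file.  A fitted rule is
serialized as a JSON document carrying only the selected genes' centroid
parameters, which is sufficient to score new specimens without the training
data.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CentroidSet,
    ExpressionData,
    InvalidInputError,
    RuleComponents,
    score_specimens,
)
from .evaluation import RelativeUtilityCurve, RocBand
from .simulation import GeneFrequencyTable

__all__ = [
    "read_matrix",
    "read_expression",
    "write_expression",
    "rule_to_dict",
    "rule_from_dict",
    "write_rule",
    "read_rule",
    "align_to_rule",
    "write_roc_band",
    "write_ru_curve",
    "write_gene_frequencies",
    "write_scores",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _dedupe(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            new = f"{g}.{seen[g]}"
            warnings.warn(f"duplicated gene id {g!r} renamed to {new!r}", stacklevel=3)
            out.append(new)
        else:
            seen[g] = 0
            out.append(g)
    return out


def read_matrix(path) -> pd.DataFrame:
    """One expression matrix: first column gene ids, remaining columns numeric.

    Non-numeric cells are reported with their file line number (header is
    line 1).  Duplicate gene ids are suffixed ``.1``, ``.2``, ... with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
        col = bad.columns[int(np.flatnonzero(bad.iloc[row].to_numpy())[0])]
        raise InvalidInputError(
            f"{path}: non-numeric value {df.iloc[row][col]!r} in column {col!r}, "
            f"line {row + 2}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.flatnonzero(numeric.isna().any(axis=1))[0])
        raise InvalidInputError(f"{path}: missing value at line {row + 2}")
    numeric.index = _dedupe([str(i) for i in numeric.index])
    return numeric


def read_expression(
    path0,
    path1=None,
    gene_names_path=None,
    classes_path=None,
    class_labels: tuple[str, str] | None = None,
) -> ExpressionData:
    """Load a two-class dataset.

    Two dialects:

    * two per-class matrices (``path0``, ``path1``): gene rows are matched
      by identifier; a differing row order is reordered with a warning;
    * one combined matrix (``path0``) plus ``classes_path``, a two-column
      file (specimen id, class label) assigning each specimen column to one
      of exactly two classes; the first label encountered in file order is
      class 0.

    ``gene_names_path`` (one name per line) optionally replaces the gene
    identifiers of both matrices.
    """
    df0 = read_matrix(path0)
    if path1 is None:
        if classes_path is None:
            raise InvalidInputError("need either a second matrix or a class file")
        df0, df1, class_labels = _split_by_classes(df0, classes_path, class_labels)
    else:
        df1 = read_matrix(path1)
        if df0.shape[0] != df1.shape[0]:
            raise InvalidInputError(
                f"gene-row mismatch: {df0.shape[0]} vs {df1.shape[0]} rows"
            )
        if not df0.index.equals(df1.index):
            if set(df0.index) == set(df1.index):
                warnings.warn(
                    "class-1 matrix rows reordered to match the class-0 matrix",
                    stacklevel=2,
                )
                df1 = df1.loc[df0.index]
            else:
                missing = sorted(set(df0.index) ^ set(df1.index))[:5]
                raise InvalidInputError(
                    f"gene ids differ between class files (e.g. {missing})"
                )
    ids = [str(i) for i in df0.index]
    if gene_names_path is not None:
        names = [
            line.strip()
            for line in Path(gene_names_path).read_text().splitlines()
            if line.strip()
        ]
        if len(names) != len(ids):
            raise InvalidInputError(
                f"gene-name list has {len(names)} entries for {len(ids)} genes"
            )
        ids = _dedupe(names)
    labels = class_labels or ("class0", "class1")
    return ExpressionData(df0.to_numpy(float), df1.to_numpy(float), tuple(ids), labels)


def _split_by_classes(df, classes_path, class_labels):
    assign = pd.read_csv(Path(classes_path), sep=None, engine="python", header=None)
    if assign.shape[1] < 2:
        raise InvalidInputError("class file needs two columns: specimen, class")
    # tolerate a header row
    if str(assign.iloc[0, 0]) not in df.columns:
        assign = assign.iloc[1:]
    mapping = dict(zip(assign.iloc[:, 0].astype(str), assign.iloc[:, 1].astype(str)))
    missing = [c for c in df.columns if str(c) not in mapping]
    if missing:
        raise InvalidInputError(f"specimens without class assignment: {missing[:5]}")
    ordered_labels = list(dict.fromkeys(mapping[str(c)] for c in df.columns))
    if len(ordered_labels) != 2:
        raise InvalidInputError(
            f"expected exactly two classes, got {ordered_labels}"
        )
    if class_labels is None:
        class_labels = (ordered_labels[0], ordered_labels[1])
    cols0 = [c for c in df.columns if mapping[str(c)] == class_labels[0]]
    cols1 = [c for c in df.columns if mapping[str(c)] == class_labels[1]]
    return df[cols0], df[cols1], class_labels


def write_expression(data: ExpressionData, path0, path1) -> None:
    """Write the two class matrices as TSV/CSV (inverse of two-file reading)."""
    for path, mat, n in ((path0, data.class0, data.n0), (path1, data.class1, data.n1)):
        path = Path(path)
        df = pd.DataFrame(
            mat, index=list(data.gene_ids), columns=[f"s{i + 1}" for i in range(n)]
        )
        df.index.name = "gene"
        df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# rule serialization


def rule_to_dict(rule: RuleComponents) -> dict:
    cs = rule.centroids
    g = np.asarray(rule.genes)
    ids = rule.gene_ids or tuple(str(i) for i in rule.genes)
    return {
        "gene_ids": list(ids),
        "c0": cs.c0[g].tolist(),
        "c1": cs.c1[g].tolist(),
        "v0": cs.v0[g].tolist(),
        "v1": cs.v1[g].tolist(),
        "v_pooled": cs.v_pooled[g].tolist(),
        "n0": int(cs.n0),
        "n1": int(cs.n1),
        "distance_measure": int(rule.distance_measure),
        "score_formula": int(rule.score_formula),
        "cutpoint": float(rule.cutpoint),
    }


def rule_from_dict(doc: dict) -> RuleComponents:
    cs = CentroidSet(
        np.asarray(doc["c0"], float),
        np.asarray(doc["c1"], float),
        np.asarray(doc["v0"], float),
        np.asarray(doc["v1"], float),
        np.asarray(doc["v_pooled"], float),
        int(doc["n0"]),
        int(doc["n1"]),
        tuple(doc["gene_ids"]),
    )
    return RuleComponents(
        cs,
        tuple(range(len(doc["gene_ids"]))),
        int(doc["distance_measure"]),
        int(doc["score_formula"]),
        float(doc["cutpoint"]),
    )


def write_rule(rule: RuleComponents, path) -> None:
    Path(path).write_text(json.dumps(rule_to_dict(rule), indent=2) + "\n")


def read_rule(path) -> RuleComponents:
    return rule_from_dict(json.loads(Path(path).read_text()))


def align_to_rule(rule: RuleComponents, df: pd.DataFrame) -> np.ndarray:
    """Rows of ``df`` (genes x specimens) matching the rule's genes, in order."""
    ids = rule.gene_ids
    missing = [g for g in ids if g not in df.index]
    if missing:
        raise InvalidInputError(f"input lacks genes required by the rule: {missing}")
    return df.loc[list(ids)].to_numpy(float)


def score_frame(rule: RuleComponents, df: pd.DataFrame) -> pd.DataFrame:
    """Scores and class calls for new specimens keyed by the rule's gene ids."""
    X = align_to_rule(rule, df)
    sub = RuleComponents(
        rule.centroids.subset(rule.genes),
        tuple(range(len(rule.genes))),
        rule.distance_measure,
        rule.score_formula,
        rule.cutpoint,
    )
    scores = score_specimens(X, sub)
    return pd.DataFrame(
        {
            "specimen": list(df.columns),
            "score": scores,
            "class": (scores >= rule.cutpoint).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# tabular outputs


def write_roc_band(band: RocBand, path) -> None:
    pd.DataFrame(
        {
            "fpr": band.fpr_grid,
            "mean_tpr": band.mean_tpr,
            "sd_tpr": band.sd_tpr,
            "lower": band.lower,
            "upper": band.upper,
        }
    ).to_csv(path, sep="\t", index=False)


def write_ru_curve(ru: RelativeUtilityCurve, path) -> None:
    pd.DataFrame(
        {"risk_threshold": ru.risk_thresholds, "relative_utility": ru.ru}
    ).to_csv(path, sep="\t", index=False)


def write_gene_frequencies(table: GeneFrequencyTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def write_scores(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
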