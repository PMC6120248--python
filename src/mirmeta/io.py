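"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices are TSV with features in rows and a header of sample IDs;
labels are two-column TSV (sample, group); meta-analysis study rows are CSV in
the layout study,n1,mean1,sd1,n2,mean2,sd2,sample_type where arm 1 is the case
(disease) arm; 2x2 diagnostic tables are CSV (study,tp,fp,fn,tn); networks are
two- or three-column edge-list TSV; gene sets are GMT.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .datatypes import ArmSummary, Diag2x2, ExpressionCohort, StudyRow, ValidationError


# -- expression matrices ----------------------------------------------------

def write_expression(cohort: ExpressionCohort, matrix_path, labels_path) -> None:
    cohort.values.to_csv(matrix_path, sep="\t", index_label="feature")
    lab = cohort.sample_groups.rename("group").rename_axis("sample").reset_index()
    lab.to_csv(labels_path, sep="\t", index=False)


def read_expression(matrix_path, labels_path) -> ExpressionCohort:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t")
    groups = pd.Series(lab["group"].values, index=lab["sample"].astype(str))
    values.columns = values.columns.astype(str)
    values.index.name = None
    return ExpressionCohort(values=values, sample_groups=groups)


# -- meta-analysis study rows ----------------------------------------------

def study_rows_from_frame(df: pd.DataFrame) -> list[StudyRow]:
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            StudyRow(
                study_id=str(rec.study),
                case=ArmSummary(int(rec.n1), float(rec.mean1), float(rec.sd1)),
                control=ArmSummary(int(rec.n2), float(rec.mean2), float(rec.sd2)),
                sample_type=str(getattr(rec, "sample_type", "tissue")),
                source=str(getattr(rec, "source", "") or ""),
            )
        )
    return rows


def read_study_rows(path) -> list[StudyRow]:
    return study_rows_from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_study_rows(rows: list[StudyRow], path) -> None:
    pd.DataFrame(
        [
            {
                "study": r.study_id,
                "n1": r.case.n, "mean1": r.case.mean, "sd1": r.case.sd,
                "n2": r.control.n, "mean2": r.control.mean, "sd2": r.control.sd,
                "sample_type": r.sample_type,
                "source": r.source,
            }
            for r in rows
        ]
    ).to_csv(path, index=False, float_format="%.17g")


# -- 2x2 diagnostic tables --------------------------------------------------

def read_diag2x2(path) -> list[Diag2x2]:
    df = pd.read_csv(path)
    return [
        Diag2x2(str(r.study), int(r.tp), int(r.fp), int(r.fn), int(r.tn))
        for r in df.itertuples(index=False)
    ]


def write_diag2x2(studies: list[Diag2x2], path) -> None:
    pd.DataFrame(
        [{"study": s.study_id, "tp": s.tp, "fp": s.fp, "fn": s.fn, "tn": s.tn} for s in studies]
    ).to_csv(path, index=False)


# -- networks ---------------------------------------------------------------

def read_edge_list(path, score_threshold: float | None = None) -> list[tuple[str, str]]:
    """Two-column edge-list TSV; a third column is read as a confidence score
    and filtered when ``score_threshold`` is given."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("edge list needs at least two columns")
    if score_threshold is not None:
        if df.shape[1] < 3:
            raise ValidationError("score threshold given but no score column present")
        df = df[df.iloc[:, 2].astype(float) >= score_threshold]
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_edge_list(edges, path) -> None:
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)


# -- gene sets --------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        collection[parts[0]] = {g for g in parts[2:] if g}
    return collection


def write_gmt(collection: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gene_list(path) -> set[str]:
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}


# -- packaged case-study tables --------------------------------------------

def load_case_study(name: str) -> pd.DataFrame:
    """Load a packaged example table.

    ``"meta_studies"`` -- per-study (n, mean, SD) rows for the two-arm
    miR-17-5p gastric-cancer meta-analysis (13 tissue + 3 serum/blood studies).
    ``"clinical_summaries"`` -- per-group (n, mean, SD) rows of miR-17
    expression against clinicopathological features in the sequencing cohort.
    """
    fname = {
        "meta_studies": "mir17_meta_studies.csv",
        "clinical_summaries": "mir17_clinical_summaries.csv",
    }[name]
    with resources.files("mirmeta.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)
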