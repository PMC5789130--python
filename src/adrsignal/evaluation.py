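"""Evaluation of signal lists against a labelled reference standard.

A reference standard is a set of drug–ADR pairs labelled positive (a
documented adverse reaction) or negative (no such evidence).  Ranking
quality is measured by the area under the ROC curve (Mann–Whitney form,
ties counted 1/2); fixed-threshold performance uses the conventional
EB05 > 2 signal rule (strict inequality).  Per-ADR AUCs and their mean
are reported alongside the pooled AUC, and a per-year score series can
be scanned for the earliest year a pair is called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "auc",
    "attach_scores",
    "evaluate_scores",
    "call_signals",
    "detection_timeline",
    "read_reference",
    "write_reference",
    "EvalReport",
]

REFERENCE_COLUMNS = ["drug_id", "adr_id", "label"]


@dataclass
class EvalReport:
    """Overall and per-ADR AUCs plus threshold-rule performance."""

    auc: float
    per_adr_auc: dict[str, float]
    mean_adr_auc: float
    called: pd.DataFrame | None = None
    precision: float | None = None
    n_true_positive: int | None = None
    n_false_positive: int | None = None

    def summary(self) -> str:
        lines = [f"pooled AUC: {self.auc:.4f}", f"mean per-ADR AUC: {self.mean_adr_auc:.4f}"]
        for adr, a in sorted(self.per_adr_auc.items()):
            lines.append(f"  AUC[{adr}]: {a:.4f}")
        if self.called is not None:
            lines.append(f"called signals: {len(self.called)}")
            if self.precision is None:
                lines.append("precision: undefined (no called pair in reference)")
            else:
                lines.append(
                    f"precision: {self.precision:.4f} "
                    f"({self.n_true_positive} TP / {self.n_false_positive} FP)"
                )
        return "\n".join(lines)


def auc(labels, scores) -> float:
    """Area under the ROC curve (Mann–Whitney rank statistic, ties = 1/2)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(y, s))


def attach_scores(
    reference: pd.DataFrame,
    scores: pd.DataFrame,
    score_field: str = "ebgm",
    *,
    missing: str = "min_minus_eps",
) -> pd.DataFrame:
    """Join reference pairs with their scores.

    Reference pairs that were never scored (the pair never co-occurred)
    are either assigned the minimum observed score minus a small epsilon
    (``min_minus_eps``, the default — absence of evidence ranks lowest
    for every method symmetrically) or dropped (``exclude``).
    """
    if missing not in ("min_minus_eps", "exclude"):
        raise ValueError(f"unknown missing-score policy {missing!r}")
    merged = reference.merge(
        scores[["drug_id", "adr_id", score_field]], on=["drug_id", "adr_id"], how="left"
    )
    if missing == "exclude":
        return merged.dropna(subset=[score_field]).reset_index(drop=True)
    observed = merged[score_field].dropna()
    if observed.empty:
        raise ValueError("no reference pair has a score")
    fill = float(observed.min()) - 1e-9 * max(1.0, abs(float(observed.min())))
    merged[score_field] = merged[score_field].fillna(fill)
    return merged


def evaluate_scores(
    scores: pd.DataFrame,
    reference: pd.DataFrame,
    score_field: str = "ebgm",
    *,
    missing: str = "min_minus_eps",
) -> EvalReport:
    """Pooled AUC and per-ADR AUCs of a score table against a reference."""
    merged = attach_scores(reference, scores, score_field, missing=missing)
    overall = auc(merged["label"], merged[score_field])
    per_adr: dict[str, float] = {}
    for adr, grp in merged.groupby("adr_id"):
        if grp["label"].nunique() == 2:
            per_adr[str(adr)] = auc(grp["label"], grp[score_field])
    mean_adr = float(np.mean(list(per_adr.values()))) if per_adr else float("nan")
    return EvalReport(auc=overall, per_adr_auc=per_adr, mean_adr_auc=mean_adr)


def call_signals(
    scores: pd.DataFrame,
    *,
    field: str = "eb05",
    threshold: float = 2.0,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Pairs whose ``field`` strictly exceeds ``threshold``.

    When a reference is supplied, precision is computed over called
    pairs that appear in the reference; it is None (undefined) when no
    called pair does.
    """
    if field not in scores.columns:
        raise ValueError(f"scores lack field {field!r}")
    called = scores[scores[field] > threshold].reset_index(drop=True)
    if reference is None:
        return called, None
    merged = called.merge(reference[REFERENCE_COLUMNS], on=["drug_id", "adr_id"], how="inner")
    if merged.empty:
        return called, None
    return called, float(merged["label"].mean())


def detection_timeline(
    per_year_scores: Mapping[int, pd.DataFrame],
    drug_id: str,
    adr_id: str,
    *,
    field: str = "eb05",
    threshold: float = 2.0,
) -> int | None:
    """Earliest year in which the signal rule fires for the pair (else None)."""
    seen = False
    for year in sorted(per_year_scores):
        df = per_year_scores[year]
        row = df[(df["drug_id"] == drug_id) & (df["adr_id"] == adr_id)]
        if row.empty:
            continue
        seen = True
        if float(row.iloc[0][field]) > threshold:
            return int(year)
    if not seen:
        raise ValueError(f"pair ({drug_id}, {adr_id}) absent from every year")
    return None


def read_reference(path, *, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype={"drug_id": str, "adr_id": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.duplicated(["drug_id", "adr_id"]).any():
        raise ValueError(f"{path}: duplicate (drug, adr) pairs")
    return df


def write_reference(reference: pd.DataFrame, path, *, delimiter: str = "\t") -> None:
    cols = [c for c in ["drug_id", "adr_id", "label", "outcome_group"] if c in reference.columns]
    reference[cols].to_csv(path, sep=delimiter, index=False)
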