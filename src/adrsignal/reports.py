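"""Spontaneous case reports and drug–ADR 2×2 contingency statistics.

A spontaneous reporting system (SRS) database is a collection of case
reports, each mentioning a set of drugs and a set of adverse drug
reactions (ADRs).  Disproportionality analysis reduces the database, per
drug–ADR pair, to a 2×2 contingency table

    =====================  ==========  =============
    .                      with ADR    without ADR
    =====================  ==========  =============
    report with drug       n00         n01
    report without drug    n10         n11
    =====================  ==========  =============

together with the expected count under independence
``E = (n00+n01)(n00+n10)/n++``, the baseline of the relative reporting
ratio.  Counts are in units of distinct reports: a drug or ADR repeated
within one report counts once.

Three counting modes are supported.  ``cooccurrence`` credits every drug
in a report for every ADR in it.  ``assigned`` credits, per ADR
occurrence, only the single "major" drug chosen by an
:class:`Assignment` (or fractional credit through ``weights``), while
the report still counts toward the drug's marginal total — the other
drugs of the report move to the drug-without-ADR cell.
``primary_suspect`` uses the reporter-designated suspect drug where one
was recorded and falls back to plain co-occurrence for ADRs without one.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaseReport",
    "Assignment",
    "build_contingency",
    "expected_count",
    "read_reports",
    "write_reports",
    "read_contingency",
    "write_contingency",
]

_WEIGHT_TOL = 1e-6


def _dedupe(items: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(str(x), None)
    return tuple(seen)


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous report: drugs, ADRs, year, optional suspect map.

    ``primary_suspect`` maps ADR id → the drug the reporter designated
    as the primary suspect for that ADR; keys must be among ``adrs`` and
    values among ``drugs``.  Drug and ADR lists are deduplicated while
    preserving order.
    """

    report_id: str
    year: int
    drugs: tuple[str, ...]
    adrs: tuple[str, ...]
    primary_suspect: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", _dedupe(self.drugs))
        object.__setattr__(self, "adrs", _dedupe(self.adrs))
        if not self.drugs:
            raise ValueError(f"report {self.report_id!r}: empty drug set")
        if not self.adrs:
            raise ValueError(f"report {self.report_id!r}: empty ADR set")
        if self.primary_suspect is not None:
            ps = dict(self.primary_suspect)
            drugs, adrs = set(self.drugs), set(self.adrs)
            for adr, drug in ps.items():
                if adr not in adrs:
                    raise ValueError(
                        f"report {self.report_id!r}: suspect key {adr!r} not among ADRs"
                    )
                if drug not in drugs:
                    raise ValueError(
                        f"report {self.report_id!r}: suspect drug {drug!r} not among drugs"
                    )
            object.__setattr__(self, "primary_suspect", ps)


@dataclass
class Assignment:
    """Map (report_id, adr_id) → the single major drug for that ADR occurrence."""

    pairs: dict[tuple[str, str], str]
    iteration: int = 0

    def drug_for(self, report_id: str, adr_id: str) -> str:
        return self.pairs[(report_id, adr_id)]


def expected_count(
    n00: float, n01: float, n10: float, n11: float, *, strict_margins: bool = False
) -> float:
    """Expected n00 under drug/ADR independence.

    Default uses the with-ADR column: E = (n00+n01)(n00+n10)/n++.  With
    ``strict_margins=True`` the second margin is the without-ADR column
    (n01+n11) instead — an audit switch, not a recommended baseline.
    """
    total = n00 + n01 + n10 + n11
    if total <= 0:
        raise ValueError("zero grand total")
    col = (n01 + n11) if strict_margins else (n00 + n10)
    return (n00 + n01) * col / total


def _validate_weights(
    reports: Sequence[CaseReport],
    weights: Mapping[tuple[str, str, str], float],
) -> None:
    sums: dict[tuple[str, str], float] = {}
    for (rid, adr, drug), w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for ({rid}, {adr}, {drug})")
        sums[(rid, adr)] = sums.get((rid, adr), 0.0) + w
    for key, s in sums.items():
        if abs(s - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights for {key} sum to {s}, expected 1 ± {_WEIGHT_TOL}")


def build_contingency(
    reports: Sequence[CaseReport],
    mode: str = "cooccurrence",
    assignment: Assignment | None = None,
    weights: Mapping[tuple[str, str, str], float] | None = None,
    *,
    include_zero_pairs: bool = False,
    strict_margins: bool = False,
) -> pd.DataFrame:
    """Build per-pair 2×2 contingency statistics from case reports.

    Parameters
    ----------
    reports
        Non-empty collection of :class:`CaseReport`.
    mode
        ``cooccurrence``, ``assigned`` or ``primary_suspect``.
    assignment
        Required for ``assigned`` mode (unless ``weights`` given); must
        cover every (report, ADR) occurrence.
    weights
        Optional fractional credit, ``(report_id, adr_id, drug_id) → w``
        with the weights per (report, ADR) summing to 1; used by the
        MCEM cumulative-mean counting.  Implies ``assigned`` semantics.
    include_zero_pairs
        If True the output covers the full drug × ADR grid, not just
        pairs that co-occur at least once (needed when scoring against a
        reference standard whose negatives may never co-occur).
    strict_margins
        Compute E with the literal without-ADR margin (audit switch).

    Returns
    -------
    DataFrame with columns ``drug_id, adr_id, n00, n01, n10, n11, E``
    (plus margins ``n_drug``, ``n_adr``, ``n_total``), one row per pair.
    Margins never depend on the mode; only n00 is redistributed.
    """
    if len(reports) == 0:
        raise ValueError("empty report collection")
    if mode not in ("cooccurrence", "assigned", "primary_suspect"):
        raise ValueError(f"unknown mode {mode!r}")

    n_total = len(reports)
    n_drug: Counter[str] = Counter()
    n_adr: Counter[str] = Counter()
    cooc: Counter[tuple[str, str]] = Counter()
    for rep in reports:
        n_drug.update(rep.drugs)
        n_adr.update(rep.adrs)
        for d in rep.drugs:
            for a in rep.adrs:
                cooc[(d, a)] += 1

    if mode == "cooccurrence":
        n00: dict[tuple[str, str], float] = dict(cooc)
    elif mode == "assigned":
        n00 = {}
        if weights is not None:
            _validate_weights(reports, weights)
            known = {(r.report_id, d) for r in reports for d in r.drugs}
            occs = {(r.report_id, a) for r in reports for a in r.adrs}
            for (rid, adr, drug), w in weights.items():
                if (rid, drug) not in known:
                    raise ValueError(f"weight references unknown report/drug ({rid}, {drug})")
                if (rid, adr) not in occs:
                    raise ValueError(f"weight references unknown ADR occurrence ({rid}, {adr})")
                n00[(drug, adr)] = n00.get((drug, adr), 0.0) + w
        else:
            if assignment is None:
                raise ValueError("mode='assigned' requires an assignment or weights")
            by_id = {r.report_id: r for r in reports}
            for rep in reports:
                for a in rep.adrs:
                    key = (rep.report_id, a)
                    if key not in assignment.pairs:
                        raise ValueError(f"assignment missing occurrence {key}")
            for (rid, adr), drug in assignment.pairs.items():
                rep = by_id.get(rid)
                if rep is None:
                    raise ValueError(f"assignment references unknown report {rid!r}")
                if drug not in rep.drugs:
                    raise ValueError(
                        f"assignment for ({rid}, {adr}) names drug {drug!r} not in report"
                    )
                n00[(drug, adr)] = n00.get((drug, adr), 0.0) + 1.0
    else:  # primary_suspect, with co-occurrence fallback per ADR
        n00 = {}
        for rep in reports:
            ps = rep.primary_suspect or {}
            for a in rep.adrs:
                if a in ps:
                    key = (ps[a], a)
                    n00[key] = n00.get(key, 0.0) + 1.0
                else:
                    for d in rep.drugs:
                        n00[(d, a)] = n00.get((d, a), 0.0) + 1.0

    if include_zero_pairs:
        universe = [(d, a) for d in sorted(n_drug) for a in sorted(n_adr)]
    else:
        universe = sorted(cooc)

    drug_ids = [d for d, _ in universe]
    adr_ids = [a for _, a in universe]
    n00_arr = np.array([n00.get(p, 0.0) for p in universe])
    nd = np.array([n_drug[d] for d in drug_ids], dtype=float)
    na = np.array([n_adr[a] for a in adr_ids], dtype=float)
    n01 = nd - n00_arr
    n10 = na - n00_arr
    n11 = n_total - nd - na + n00_arr
    col = (n_total - na) if strict_margins else na
    e = nd * col / n_total

    out = pd.DataFrame(
        {
            "drug_id": drug_ids,
            "adr_id": adr_ids,
            "n00": n00_arr,
            "n01": n01,
            "n10": n10,
            "n11": n11,
            "n_drug": nd,
            "n_adr": na,
            "n_total": float(n_total),
            "E": e,
        }
    )
    if weights is None and not out.empty:
        # integer-valued counts in the unweighted modes
        for c in ("n00", "n01", "n10", "n11"):
            out[c] = out[c].round().astype(float)
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O


def _format_suspects(ps: Mapping[str, str] | None) -> str:
    if not ps:
        return ""
    return "|".join(f"{adr}:{drug}" for adr, drug in ps.items())


def write_reports(reports: Sequence[CaseReport], path, *, delimiter: str = "\t") -> None:
    """Write reports as UTF-8 delimited text with pipe-separated lists."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["report_id", "year", "drugs", "adrs", "primary_suspect"])
        for rep in reports:
            w.writerow(
                [
                    rep.report_id,
                    rep.year,
                    "|".join(rep.drugs),
                    "|".join(rep.adrs),
                    _format_suspects(rep.primary_suspect),
                ]
            )


def read_reports(path, *, delimiter: str = "\t") -> list[CaseReport]:
    """Read a report table; errors cite 1-based line numbers."""
    reports: list[CaseReport] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rdr = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(rdr)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        expected = ["report_id", "year", "drugs", "adrs", "primary_suspect"]
        if [h.strip() for h in header] != expected:
            raise ValueError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, row in enumerate(rdr, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            rid, year_s, drugs_s, adrs_s, ps_s = row
            try:
                year = int(year_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad year {year_s!r}") from None
            ps: dict[str, str] | None = None
            if ps_s.strip():
                ps = {}
                for tok in ps_s.split("|"):
                    if ":" not in tok:
                        raise ValueError(
                            f"{path}:{lineno}: bad primary_suspect token {tok!r}"
                        )
                    adr, drug = tok.split(":", 1)
                    ps[adr] = drug
            try:
                reports.append(
                    CaseReport(
                        report_id=rid,
                        year=year,
                        drugs=tuple(drugs_s.split("|")) if drugs_s else (),
                        adrs=tuple(adrs_s.split("|")) if adrs_s else (),
                        primary_suspect=ps,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not reports:
        raise ValueError(f"{path}: no reports")
    return reports


def write_contingency(stats: pd.DataFrame, path, *, delimiter: str = "\t") -> None:
    cols = ["drug_id", "adr_id", "n00", "n01", "n10", "n11", "E"]
    stats[cols].to_csv(path, sep=delimiter, index=False)


def read_contingency(path, *, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype={"drug_id": str, "adr_id": str})
    df["n_drug"] = df["n00"] + df["n01"]
    df["n_adr"] = df["n00"] + df["n10"]
    df["n_total"] = df[["n00", "n01", "n10", "n11"]].sum(axis=1)
    return df
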