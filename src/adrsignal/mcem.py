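"""Monte-Carlo EM filtering of concomitant-drug confounders.

Spontaneous reports usually mention several drugs per ADR, and
co-occurrence counting lets confounders inherit the causal drug's
association.  Under the assumption that each ADR occurrence has a single
major drug, the MCEM loop alternates:

  E-step (Monte Carlo): for every (report, ADR) occurrence, draw one
  major drug with probability proportional to the current MGPS score of
  each candidate drug in that report (normalised within the report);

  M-step: rebuild the contingency counts from the sampled assignments
  (either the latest draw or a running mean of draws) and refit the
  mixture prior by maximum marginal likelihood, then rescore.

The loop stops when the attained marginal log-likelihood changes by
less than ``tol`` between consecutive iterations, mirroring the usual
heuristic thresholds (1e-3 … 1e-5).  With ``cumulative_mean`` counting
the per-pair counts are fractional running means of the sampled
one-hot assignments, which damps Monte Carlo noise; the marginal
density handles fractional counts through Γ(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mgps
from .reports import Assignment, CaseReport, build_contingency

__all__ = [
    "McemConfig",
    "McemTrace",
    "sampling_probabilities",
    "sample_assignment",
    "run_mcem",
]


@dataclass(frozen=True)
class McemConfig:
    """Knobs of the MCEM loop.

    tol is the stopping threshold on the change of the fitted prior's
    marginal log-likelihood; burn_in iterations are excluded from the
    cumulative averaging; score_floor keeps unscored or near-zero pairs
    samplable (no zero-probability lock-in).
    """

    max_iter: int = 30
    tol: float = 1e-3
    burn_in: int = 1
    count_mode: str = "cumulative_mean"
    seed: int = 0
    score_floor: float = 1e-6
    sampling_score: str = "ebgm"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.burn_in >= self.max_iter:
            raise ValueError("burn_in must be < max_iter")
        if self.count_mode not in ("last_sample", "cumulative_mean"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if self.sampling_score not in ("ebgm", "eb05"):
            raise ValueError(f"unknown sampling_score {self.sampling_score!r}")
        if self.score_floor <= 0:
            raise ValueError("score_floor must be positive")


@dataclass
class McemTrace:
    """Per-iteration diagnostics plus the terminal state of the loop."""

    logliks: list[float]
    priors: list[mgps.PriorParams]
    assignment: Assignment | None
    weights: pd.DataFrame | None
    scores: pd.DataFrame
    converged: bool
    n_iter: int


def sampling_probabilities(
    report: CaseReport,
    adr_id: str,
    scores: Mapping[tuple[str, str], float],
    floor: float = 1e-6,
) -> dict[str, float]:
    """Per-drug sampling probabilities for one ADR occurrence.

    Each drug's MGPS score for the ADR is floored at ``floor`` (pairs
    absent from the lookup get the floor) and normalised across only the
    drugs mentioned in this report.
    """
    if adr_id not in report.adrs:
        raise ValueError(f"report {report.report_id!r} does not mention ADR {adr_id!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    if not report.drugs:
        raise ValueError("empty drug set")
    raw = {d: max(scores.get((d, adr_id), floor), floor) for d in report.drugs}
    total = sum(raw.values())
    return {d: v / total for d, v in raw.items()}


# ---------------------------------------------------------------------------
# vectorised occurrence index


class _OccurrenceIndex:
    """Flat arrays over all (report, ADR) occurrences for fast sampling."""

    def __init__(self, reports: Sequence[CaseReport]):
        self.reports = list(reports)
        self.drug_ids = sorted({d for r in reports for d in r.drugs})
        self.adr_ids = sorted({a for r in reports for a in r.adrs})
        self.d_index = {d: i for i, d in enumerate(self.drug_ids)}
        self.a_index = {a: i for i, a in enumerate(self.adr_ids)}

        occ_report: list[int] = []
        occ_adr: list[int] = []
        cand: list[list[int]] = []
        for ri, rep in enumerate(reports):
            drugs = [self.d_index[d] for d in rep.drugs]
            for a in rep.adrs:
                occ_report.append(ri)
                occ_adr.append(self.a_index[a])
                cand.append(drugs)
        self.occ_report = np.asarray(occ_report, dtype=np.int64)
        self.occ_adr = np.asarray(occ_adr, dtype=np.int64)
        self.n_occ = len(cand)
        self.kmax = max(len(c) for c in cand)
        self.cand = np.zeros((self.n_occ, self.kmax), dtype=np.int64)
        self.mask = np.zeros((self.n_occ, self.kmax), dtype=bool)
        for i, c in enumerate(cand):
            self.cand[i, : len(c)] = c
            self.mask[i, : len(c)] = True

    def score_matrix(self, scores: pd.DataFrame, field: str, floor: float) -> np.ndarray:
        mat = np.full((len(self.drug_ids), len(self.adr_ids)), floor)
        di = scores["drug_id"].map(self.d_index).to_numpy()
        ai = scores["adr_id"].map(self.a_index).to_numpy()
        ok = ~(np.isnan(di.astype(float)) | np.isnan(ai.astype(float)))
        vals = np.maximum(np.asarray(scores[field], dtype=float), floor)
        mat[di[ok].astype(int), ai[ok].astype(int)] = vals[ok]
        return mat

    def sample(self, score_mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One categorical draw per occurrence; returns one-hot (n_occ, kmax)."""
        probs = score_mat[self.cand, self.occ_adr[:, None]]
        probs = np.where(self.mask, probs, 0.0)
        cum = np.cumsum(probs, axis=1)
        totals = cum[:, -1:]
        u = rng.random((self.n_occ, 1)) * totals
        choice = (cum < u).sum(axis=1)
        onehot = np.zeros_like(probs)
        onehot[np.arange(self.n_occ), choice] = 1.0
        return onehot

    def counts(self, weights: np.ndarray) -> np.ndarray:
        """Accumulate occurrence weights into an (n_drugs, n_adrs) n00 matrix."""
        mat = np.zeros((len(self.drug_ids), len(self.adr_ids)))
        w = np.where(self.mask, weights, 0.0)
        np.add.at(
            mat,
            (self.cand[self.mask], np.broadcast_to(self.occ_adr[:, None], self.cand.shape)[self.mask]),
            w[self.mask],
        )
        return mat

    def to_assignment(self, onehot: np.ndarray, iteration: int) -> Assignment:
        choice = onehot.argmax(axis=1)
        pairs: dict[tuple[str, str], str] = {}
        for i in range(self.n_occ):
            rep = self.reports[self.occ_report[i]]
            adr = self.adr_ids[self.occ_adr[i]]
            drug = self.drug_ids[self.cand[i, choice[i]]]
            pairs[(rep.report_id, adr)] = drug
        return Assignment(pairs=pairs, iteration=iteration)

    def weights_frame(self, weights: np.ndarray) -> pd.DataFrame:
        rows = []
        for i in range(self.n_occ):
            rep = self.reports[self.occ_report[i]]
            adr = self.adr_ids[self.occ_adr[i]]
            for k in range(self.kmax):
                if self.mask[i, k] and weights[i, k] > 0:
                    rows.append(
                        (rep.report_id, adr, self.drug_ids[self.cand[i, k]], weights[i, k])
                    )
        return pd.DataFrame(rows, columns=["report_id", "adr_id", "drug_id", "weight"])


def sample_assignment(
    reports: Sequence[CaseReport],
    scores: pd.DataFrame,
    rng: np.random.Generator,
    *,
    floor: float = 1e-6,
    score_field: str = "ebgm",
) -> Assignment:
    """Draw one major drug per (report, ADR) occurrence.

    Probabilities follow :func:`sampling_probabilities`; the draw is a
    single categorical sample per occurrence and is reproducible given
    the generator state.
    """
    idx = _OccurrenceIndex(reports)
    mat = idx.score_matrix(scores, score_field, floor)
    onehot = idx.sample(mat, rng)
    return idx.to_assignment(onehot, iteration=0)


def run_mcem(
    reports: Sequence[CaseReport],
    config: McemConfig | None = None,
    *,
    fit_kwargs: dict | None = None,
    strict_margins: bool = False,
) -> McemTrace:
    """Run the full MCEM confounder-filtering loop.

    Iteration 0 scores pairs from plain co-occurrence counts.  Each
    subsequent iteration samples an assignment, rebuilds n00 per
    ``config.count_mode``, refits the prior (initialised at the previous
    optimum) and rescores.  Stops when the marginal log-likelihood
    changes by less than ``config.tol``.  Identical (reports, config)
    give a bit-identical trace.
    """
    if len(reports) == 0:
        raise ValueError("empty report collection")
    config = config or McemConfig()
    fit_kwargs = dict(fit_kwargs or {})

    idx = _OccurrenceIndex(reports)
    rng = np.random.default_rng(config.seed)

    ctab = build_contingency(reports, "cooccurrence", strict_margins=strict_margins)
    prior = mgps.fit_prior(ctab, **fit_kwargs)
    need_quantiles = config.sampling_score == "eb05"
    scores = mgps.score_all(ctab, prior, compute_quantiles=need_quantiles)

    logliks = [prior.loglik]
    priors = [prior]
    prev_n00 = ctab["n00"].to_numpy(copy=True)
    di = ctab["drug_id"].map(idx.d_index).to_numpy(dtype=np.int64)
    ai = ctab["adr_id"].map(idx.a_index).to_numpy(dtype=np.int64)

    cum = np.zeros((idx.n_occ, idx.kmax))
    n_cum = 0
    onehot = None
    weights = None
    converged = False
    t = 0
    for t in range(1, config.max_iter + 1):
        mat = idx.score_matrix(scores, config.sampling_score, config.score_floor)
        onehot = idx.sample(mat, rng)
        if config.count_mode == "cumulative_mean" and t > config.burn_in:
            cum += onehot
            n_cum += 1
            weights = cum / n_cum
        else:
            weights = onehot
        n00_mat = idx.counts(weights)
        new_n00 = n00_mat[di, ai]

        ctab = ctab.copy()
        ctab["n00"] = new_n00
        ctab["n01"] = ctab["n_drug"] - new_n00
        ctab["n10"] = ctab["n_adr"] - new_n00
        ctab["n11"] = ctab["n_total"] - ctab["n_drug"] - ctab["n_adr"] + new_n00

        if np.array_equal(new_n00, prev_n00):
            # counts unchanged: the M-step optimum is unchanged too
            logliks.append(prior.loglik)
            priors.append(prior)
            converged = True
            break
        prior = mgps.fit_prior(ctab, init=prior, **{k: v for k, v in fit_kwargs.items() if k != "n_restarts"})
        scores = mgps.score_all(ctab, prior, compute_quantiles=need_quantiles)
        logliks.append(prior.loglik)
        priors.append(prior)
        prev_n00 = new_n00
        if abs(logliks[-1] - logliks[-2]) < config.tol:
            converged = True
            break

    final_scores = mgps.score_all(ctab, prior, compute_quantiles=True)
    assignment = idx.to_assignment(onehot, iteration=t) if onehot is not None else None
    wframe = (
        idx.weights_frame(weights)
        if (weights is not None and config.count_mode == "cumulative_mean")
        else None
    )
    return McemTrace(
        logliks=logliks,
        priors=priors,
        assignment=assignment,
        weights=wframe,
        scores=final_scores,
        converged=converged,
        n_iter=t,
    )
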