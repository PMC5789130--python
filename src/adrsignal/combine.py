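"""Empirical-Bayes combination of signal scores across data sources.

Each drug–ADR pair l carries scores y_lk with variances σ²_lk from
sources k = 1..K (e.g. per-year spontaneous-report scores and a claims
source).  A normal–normal hierarchical model is assumed:

    y(l) | φ_l ~ N(φ_l, σ_l²),     φ_l | θ ~ N(θ, τ²),

so the posterior-mean combined estimate is the shrinkage formula

    φ̂_l = c_l y(l) + (1 − c_l) θ,   c_l = τ² / (τ² + σ_l²).

The per-pair summary y(l) pools evidence with reliability weighting:
within one source, a pair's scores are combined by inverse-variance
weighting; across sources, each source is weighted by the reciprocal of
its mean score variance (a source that is noisy on average counts for
less), normalised so y(l) is a convex combination.  σ_l² follows by
variance propagation.  θ and τ² are estimated by EM over the summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "summary_statistic",
    "summarize_sources",
    "fit_hyperparameters",
    "combine",
    "combine_sources",
    "marginal_loglik",
    "read_source_scores",
    "write_combined",
]

TAU2_FLOOR = 1e-12

SOURCE_COLUMNS = ["source_id", "drug_id", "adr_id", "score", "variance"]


@dataclass(frozen=True)
class Hyperparameters:
    theta: float
    tau2: float
    n_iter: int
    converged: bool


def _source_mean_vars(scores: pd.DataFrame) -> pd.Series:
    """Mean of σ²_lk over each source's contributed signals."""
    return scores.groupby("source_id")["variance"].mean()


def summary_statistic(
    pair_scores: pd.DataFrame,
    source_mean_var: pd.Series | dict,
    *,
    strict_eq10: bool = False,
) -> tuple[float, float]:
    """Pool one pair's scores across sources into (y_l, σ_l²).

    Within each source the pair's scores are inverse-variance averaged
    (u_lk with variance v_lk); across sources u_lk are averaged with
    weights 1/source_mean_var[k], normalised over the sources that
    actually observed the pair.  ``strict_eq10`` keeps the weights
    unnormalised (the literal printed form; audit only).
    """
    if pair_scores.empty:
        raise ValueError("pair absent from every source")
    var = np.asarray(pair_scores["variance"], dtype=float)
    if np.any(var <= 0):
        raise ValueError("score variances must be strictly positive")
    smv = pd.Series(source_mean_var)

    u, v, w = [], [], []
    for sid, grp in pair_scores.groupby("source_id"):
        prec = 1.0 / np.asarray(grp["variance"], dtype=float)
        u.append(float(np.sum(np.asarray(grp["score"], dtype=float) * prec) / prec.sum()))
        v.append(float(1.0 / prec.sum()))
        w.append(1.0 / float(smv[sid]))
    u, v, w = np.asarray(u), np.asarray(v), np.asarray(w)
    if strict_eq10:
        y = float(np.sum(w * u))
        s2 = float(np.sum(w**2 * v))
    else:
        wn = w / w.sum()
        y = float(np.sum(wn * u))
        s2 = float(np.sum(wn**2 * v))
    return y, s2


def summarize_sources(scores: pd.DataFrame, *, strict_eq10: bool = False) -> pd.DataFrame:
    """Apply :func:`summary_statistic` to every pair in a long score table.

    ``scores`` columns: source_id, drug_id, adr_id, score, variance.
    Returns one row per (drug_id, adr_id) with columns y_l, sigma_l2.
    """
    missing = [c for c in SOURCE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"source score table lacks columns {missing}")
    smv = _source_mean_vars(scores)
    rows = []
    for (drug, adr), grp in scores.groupby(["drug_id", "adr_id"], sort=True):
        y, s2 = summary_statistic(grp, smv, strict_eq10=strict_eq10)
        rows.append((drug, adr, y, s2))
    return pd.DataFrame(rows, columns=["drug_id", "adr_id", "y_l", "sigma_l2"])


def marginal_loglik(y: np.ndarray, s2: np.ndarray, theta: float, tau2: float) -> float:
    """Σ log N(y_l; θ, τ² + σ_l²) — the EM objective, for diagnostics."""
    var = tau2 + s2
    return float(np.sum(-0.5 * (np.log(2 * np.pi * var) + (y - theta) ** 2 / var)))


def fit_hyperparameters(
    summaries: pd.DataFrame,
    *,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> Hyperparameters:
    """EM estimation of the shared prior mean θ and variance τ².

    E-step: posterior moments of each φ_l given (θ, τ²);
    M-step: θ ← mean of posterior means, τ² ← mean of posterior second
    central moments about θ.  τ² is floored at 1e-12 so c_l stays
    defined when the summaries carry no between-signal spread.
    """
    y = np.asarray(summaries["y_l"], dtype=float)
    s2 = np.asarray(summaries["sigma_l2"], dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 pair summaries to estimate hyperparameters")
    if np.any(s2 < 0):
        raise ValueError("summary variances must be non-negative")

    theta = float(np.mean(y))
    tau2 = max(float(np.var(y)), TAU2_FLOOR)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        c = tau2 / (tau2 + s2)
        m = c * y + (1.0 - c) * theta
        v = c * s2
        new_theta = float(np.mean(m))
        new_tau2 = max(float(np.mean(v + (m - new_theta) ** 2)), TAU2_FLOOR)
        if max(abs(new_theta - theta), abs(new_tau2 - tau2)) < tol:
            theta, tau2 = new_theta, new_tau2
            converged = True
            break
        theta, tau2 = new_theta, new_tau2
    return Hyperparameters(theta=theta, tau2=tau2, n_iter=it, converged=converged)


def combine(summaries: pd.DataFrame, theta: float, tau2: float) -> pd.DataFrame:
    """Shrinkage estimates φ̂_l = c_l y_l + (1 − c_l) θ per pair."""
    out = summaries.copy()
    s2 = np.asarray(out["sigma_l2"], dtype=float)
    c = tau2 / (tau2 + s2)
    out["c_l"] = c
    out["phi_hat"] = c * np.asarray(out["y_l"], dtype=float) + (1.0 - c) * theta
    out["theta"] = theta
    out["tau2"] = tau2
    return out


def combine_sources(
    scores: pd.DataFrame,
    *,
    pairs: str = "union",
    strict_eq10: bool = False,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> pd.DataFrame:
    """Full combination stage: summarise, fit (θ, τ²) by EM, shrink.

    ``pairs`` selects the population the hierarchical model is fitted
    on: ``union`` keeps every pair seen by at least one source
    (source weights renormalised where a source is missing), while
    ``intersection`` restricts to pairs scored by every source — the
    usual choice when one source covers a small curated pair list, so
    that the between-signal variance τ² is estimated on the population
    actually being combined rather than swamped by single-source
    background pairs.

    Returns one row per pair with y_l, sigma_l2, c_l, phi_hat, theta,
    tau2, plus EM metadata in ``DataFrame.attrs["hyperparameters"]``.
    """
    if pairs not in ("union", "intersection"):
        raise ValueError(f"unknown pair policy {pairs!r}")
    if pairs == "intersection":
        n_sources = scores["source_id"].nunique()
        seen = scores.groupby(["drug_id", "adr_id"])["source_id"].nunique()
        keep = seen[seen == n_sources].index
        scores = scores.set_index(["drug_id", "adr_id"]).loc[keep].reset_index()
    summaries = summarize_sources(scores, strict_eq10=strict_eq10)
    hp = fit_hyperparameters(summaries, tol=tol, max_iter=max_iter)
    out = combine(summaries, hp.theta, hp.tau2)
    out.attrs["hyperparameters"] = hp
    return out


def from_mgps_scores(scores: pd.DataFrame, prior, source_id: str = "SRS") -> pd.DataFrame:
    """Turn an MGPS score table into a source-score table for combination.

    The score is EBlog2 (posterior mean of log2 λ, an unbounded, roughly
    symmetric scale) and the variance is the posterior variance of
    log2 λ under the two-gamma mixture.
    """
    from . import mgps as _mgps

    n = np.asarray(scores["n00"], dtype=float)
    e = np.asarray(scores["E"], dtype=float)
    out = pd.DataFrame(
        {
            "source_id": source_id,
            "drug_id": scores["drug_id"].to_numpy(),
            "adr_id": scores["adr_id"].to_numpy(),
            "score": np.asarray(scores["eblog2"], dtype=float),
            "variance": _mgps.posterior_log2_var(n, e, prior),
        }
    )
    return out


def read_source_scores(paths, *, delimiter: str = "\t") -> pd.DataFrame:
    """Read and concatenate one or more source-score tables."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep=delimiter, dtype={"source_id": str, "drug_id": str, "adr_id": str})
        missing = [c for c in SOURCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{p}: missing columns {missing}")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_combined(combined: pd.DataFrame, path, *, delimiter: str = "\t") -> None:
    cols = ["drug_id", "adr_id", "y_l", "sigma_l2", "c_l", "phi_hat", "theta", "tau2"]
    combined[cols].to_csv(path, sep=delimiter, index=False)
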