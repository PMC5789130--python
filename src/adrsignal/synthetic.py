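"""Synthetic spontaneous-report generator with planted ground truth.

Emulates the statistical structure that confounder filtering and signal
combination assume, without any external data:

* multi-drug reports (≈48% of reports mention more than one drug);
* exactly one causal drug per ADR occurrence — every ADR appears
  spontaneously at ``background_adr_rate``, and a planted causal drug
  adds the excess probability ``background_adr_rate × (causal_rr − 1)``
  when present, so the pair's total occurrence rate is
  ``background_adr_rate × causal_rr`` and ``causal_rr = 1`` is exactly
  the null model;
* concomitant confounding — drugs are co-prescribed in clusters, so a
  causal drug's cluster-mates co-occur with its ADR far more often than
  chance and inherit a spurious association;
* under-reporting — each caused ADR is omitted from the report with
  probability ``underreporting_prob`` (the ground truth keeps only
  retained occurrences, as an unreported event leaves no trace);
* optional reporter annotation — with probability ``suspect_prob`` the
  reporter records a primary-suspect drug for a caused ADR, correct with
  probability ``suspect_accuracy`` and otherwise a random co-reported
  drug.

Multi-source score tables for the combination stage are generated as
the true log2 relative risk plus Gaussian noise with per-source spread,
so sources differ in reliability by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reports import CaseReport

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_reports",
    "make_reference_standard",
    "generate_source_scores",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic spontaneous-report world.

    Defaults emulate the sparse regime of spontaneous reporting: a wide
    drug vocabulary, rare ADRs (a few mentions per thousand reports per
    term), roughly half the reports mentioning more than one drug,
    drugs co-prescribed in small clusters, and a quarter of caused
    events never reported.  Per-pair counts land in the low single
    digits, where shrinkage and confounding actually bite.
    """

    n_reports: int = 20000
    n_drugs: int = 200
    n_adrs: int = 50
    n_causal_pairs: int = 25
    causal_rr: float = 5.0
    background_adr_rate: float = 0.004
    multi_drug_fraction: float = 0.48
    max_drugs_per_report: int = 4
    n_clusters: int = 50
    p_cluster: float = 0.9
    underreporting_prob: float = 0.25
    suspect_prob: float = 0.5
    suspect_accuracy: float = 0.7
    year_range: tuple[int, int] = (2007, 2014)
    n_sources: int = 2
    source_noise_sd: tuple[float, ...] = (1.0, 1.5)
    negative_ratio: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "background_adr_rate",
            "multi_drug_fraction",
            "p_cluster",
            "underreporting_prob",
            "suspect_prob",
            "suspect_accuracy",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.causal_rr < 1.0:
            raise ValueError("causal_rr must be >= 1")
        if self.n_causal_pairs > min(self.n_drugs, self.n_adrs):
            raise ValueError("n_causal_pairs exceeds available distinct drugs/ADRs")
        if self.max_drugs_per_report < 2:
            raise ValueError("max_drugs_per_report must be >= 2")
        if len(self.source_noise_sd) < self.n_sources:
            raise ValueError("need one noise s.d. per source")


@dataclass
class GroundTruth:
    """Planted causal pairs and the per-occurrence causal drug."""

    causal_pairs: dict[tuple[str, str], float]  # (drug, adr) -> true log2 RR
    per_report_causes: dict[tuple[str, str], str]  # (report_id, adr_id) -> drug_id
    drug_ids: list[str] = field(default_factory=list)
    adr_ids: list[str] = field(default_factory=list)
    clusters: list[list[str]] = field(default_factory=list)  # co-prescription groups

    def true_log2_rr(self, drug_id: str, adr_id: str) -> float:
        return self.causal_pairs.get((drug_id, adr_id), 0.0)


def _check_feasible(config: SimConfig) -> None:
    if config.underreporting_prob >= 1.0:
        raise ValueError(
            "infeasible configuration: underreporting_prob=1 drops every caused ADR"
        )
    # expected ADR mentions per report; caused contribution is a lower bound of 0
    expected = config.n_adrs * config.background_adr_rate
    expected += (
        config.background_adr_rate
        * (config.causal_rr - 1.0)
        * (1.0 - config.underreporting_prob)
    )
    if expected < 1e-4:
        raise ValueError(
            f"infeasible configuration: expected ADR mentions per report ≈ {expected:.2e}"
        )


def _draw_drug_sets(config: SimConfig, clusters: np.ndarray, batch: int, rng) -> np.ndarray:
    """Batch of drug index sets, padded with -1, shape (batch, max_k).

    Each report draws 1 drug (prob 1 − multi_drug_fraction) or 2..max_k
    drugs; with probability ``p_cluster`` the drugs come from a single
    co-prescription cluster, else uniformly from the vocabulary.
    """
    kmax = config.max_drugs_per_report
    k = np.where(
        rng.random(batch) < config.multi_drug_fraction,
        rng.integers(2, kmax + 1, size=batch),
        1,
    )
    use_cluster = rng.random(batch) < config.p_cluster
    out = np.full((batch, kmax), -1, dtype=np.int64)

    # cluster draws: random order within the chosen cluster, take first k
    n_cl, cl_size = clusters.shape
    cid = rng.integers(n_cl, size=batch)
    order = np.argsort(rng.random((batch, cl_size)), axis=1)
    chosen = clusters[cid[:, None], order]
    kk = np.minimum(k, cl_size)
    for i in np.nonzero(use_cluster)[0]:
        out[i, : kk[i]] = chosen[i, : kk[i]]

    # uniform draws from the full vocabulary
    uni = np.nonzero(~use_cluster)[0]
    singles = uni[k[uni] == 1]
    out[singles, 0] = rng.integers(config.n_drugs, size=singles.size)
    for i in uni[k[uni] > 1]:
        out[i, : k[i]] = rng.choice(config.n_drugs, size=int(k[i]), replace=False)
    return out


def generate_reports(config: SimConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Generate ``n_reports`` case reports plus their planted ground truth.

    Deterministic given the config (including its seed).  Reports with
    zero retained ADRs are discarded and regeneration continues until
    ``n_reports`` are collected.  Causal pairs are planted on distinct
    drugs and distinct ADRs, so every ADR occurrence has at most one
    causal drug.
    """
    _check_feasible(config)
    rng = np.random.default_rng(config.seed)

    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    adrs = [f"A{j:03d}" for j in range(config.n_adrs)]

    # co-prescription clusters: a partition of the drug vocabulary
    perm = rng.permutation(config.n_drugs)
    cl_size = config.n_drugs // config.n_clusters
    if cl_size < 2:
        raise ValueError("clusters need at least 2 drugs each")
    clusters = perm[: cl_size * config.n_clusters].reshape(config.n_clusters, cl_size)

    # planted causal pairs on distinct drugs and distinct ADRs
    causal_drugs = rng.choice(config.n_drugs, size=config.n_causal_pairs, replace=False)
    causal_adrs = rng.choice(config.n_adrs, size=config.n_causal_pairs, replace=False)
    adr_of_drug = np.full(config.n_drugs + 1, -1, dtype=np.int64)  # slot -1 = padding
    adr_of_drug[causal_drugs] = causal_adrs
    causal_pairs = {
        (drugs[int(d)], adrs[int(a)]): float(np.log2(config.causal_rr))
        for d, a in zip(causal_drugs, causal_adrs)
    }

    # excess trigger probability on top of background, so the planted pair's
    # total occurrence rate is ≈ background_adr_rate × causal_rr
    p_excess = min(config.background_adr_rate * (config.causal_rr - 1.0), 1.0)
    reports: list[CaseReport] = []
    per_report_causes: dict[tuple[str, str], str] = {}
    years = np.arange(config.year_range[0], config.year_range[1] + 1)

    next_id = 0
    rounds = 0
    while len(reports) < config.n_reports:
        rounds += 1
        if rounds > 200:
            raise ValueError("infeasible configuration: almost every report is empty")
        batch = min(max(2 * (config.n_reports - len(reports)), 1000), 200_000)

        drug_sets = _draw_drug_sets(config, clusters, batch, rng)
        background = rng.random((batch, config.n_adrs)) < config.background_adr_rate

        # caused occurrences: a causal drug in the report triggers its ADR,
        # and the triggered event survives under-reporting
        slot_adr = adr_of_drug[drug_sets]  # (batch, kmax), -1 where none
        triggered = (slot_adr >= 0) & (rng.random(drug_sets.shape) < p_excess)
        retained = triggered & (rng.random(drug_sets.shape) >= config.underreporting_prob)
        rep_years = rng.choice(years, size=batch)
        u_suspect = rng.random(drug_sets.shape)
        u_correct = rng.random(drug_sets.shape)
        u_wrong = rng.random(drug_sets.shape)

        nonempty = np.nonzero(background.any(axis=1) | retained.any(axis=1))[0]
        for i in nonempty:
            if len(reports) >= config.n_reports:
                break
            drug_idx = [int(d) for d in drug_sets[i] if d >= 0]
            adr_set = set(np.nonzero(background[i])[0].tolist())
            rid = f"R{next_id:06d}"
            suspects: dict[str, str] = {}
            for slot in np.nonzero(retained[i])[0]:
                d = int(drug_sets[i, slot])
                a = int(slot_adr[i, slot])
                adr_set.add(a)
                per_report_causes[(rid, adrs[a])] = drugs[d]
                if u_suspect[i, slot] < config.suspect_prob:
                    if len(drug_idx) == 1 or u_correct[i, slot] < config.suspect_accuracy:
                        suspects[adrs[a]] = drugs[d]
                    else:
                        others = [x for x in drug_idx if x != d]
                        suspects[adrs[a]] = drugs[others[int(u_wrong[i, slot] * len(others))]]
            next_id += 1
            reports.append(
                CaseReport(
                    report_id=rid,
                    year=int(rep_years[i]),
                    drugs=tuple(drugs[d] for d in drug_idx),
                    adrs=tuple(adrs[a] for a in sorted(adr_set)),
                    primary_suspect=suspects or None,
                )
            )

    truth = GroundTruth(
        causal_pairs=causal_pairs,
        per_report_causes=per_report_causes,
        drug_ids=drugs,
        adr_ids=adrs,
        clusters=[[drugs[int(d)] for d in row] for row in clusters],
    )
    return reports, truth


def make_reference_standard(
    truth: GroundTruth,
    reports: list[CaseReport],
    *,
    negative_ratio: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-outcome reference standard with plausible-suspect negatives.

    Each planted pair is a positive for its ADR (outcome).  For the same
    ADR the ``negative_ratio`` non-causal drugs most often co-reported
    with it become the negatives — the synthetic analogue of a curated
    standard, whose negatives are plausible but unsupported suspects.
    By construction these are dominated by the co-prescription
    confounders, the pairs the confounder filtering must demote.  Ties
    in co-occurrence are broken by a seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    cooc: dict[tuple[str, str], int] = {}
    for r in reports:
        for d in r.drugs:
            for a in r.adrs:
                cooc[(d, a)] = cooc.get((d, a), 0) + 1
    positives = sorted(truth.causal_pairs)
    causal_set = set(positives)
    negatives: list[tuple[str, str]] = []
    for _, adr in positives:
        cands = [
            (drug, a) for (drug, a), cnt in cooc.items() if a == adr and (drug, a) not in causal_set
        ]
        tie_break = rng.permutation(len(cands))
        order = sorted(range(len(cands)), key=lambda i: (-cooc[cands[i]], tie_break[i]))
        negatives.extend(cands[i] for i in order[:negative_ratio])
    rows = [(d, a, 1, a) for d, a in positives] + [(d, a, 0, a) for d, a in negatives]
    return pd.DataFrame(rows, columns=["drug_id", "adr_id", "label", "outcome_group"])


def generate_source_scores(
    truth: GroundTruth,
    config: SimConfig,
    pairs: pd.DataFrame,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-source noisy signal scores on the true log2 relative-risk scale.

    For source k each pair's score is its true log2 RR plus N(0, sd_k²)
    noise, with the variance column set to sd_k²; the sources' noise
    levels differ so pooling weights are testable.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    pair_list = list(zip(pairs["drug_id"], pairs["adr_id"]))
    for k in range(config.n_sources):
        sd = float(config.source_noise_sd[k])
        noise = rng.normal(scale=sd, size=len(pair_list)) if sd > 0 else np.zeros(len(pair_list))
        for (d, a), eps in zip(pair_list, noise):
            rows.append((f"S{k}", d, a, truth.true_log2_rr(d, a) + eps, max(sd**2, 1e-12)))
    return pd.DataFrame(rows, columns=["source_id", "drug_id", "adr_id", "score", "variance"])
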