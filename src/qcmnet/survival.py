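"""Module-driven patient stratification and survival comparison.

Given a gene module and a patients x genes expression matrix, patients are
clustered into two groups by K-means under correlation distance (realized as
Euclidean K-means on per-patient standardized vectors, which is monotone
equivalent), and the groups' survival is compared with the two-group log-rank
test and visualized via Kaplan-Meier product-limit curves.

Clinical tables follow the TCGA convention: a patient with vital status
LIVING contributes a censored record at days_to_last_followup; any other
status contributes an event record at days_to_death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecord:
    """Per-patient time-to-event with censoring flag (event=True means death observed)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"patient {self.patient_id!r}: negative time {self.time}")


@dataclass
class KMCurve:
    """Right-continuous product-limit step function, S(0) = 1."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": np.concatenate([[0.0], self.times]),
                "survival": np.concatenate([[1.0], self.survival]),
                "at_risk": np.concatenate([[self.at_risk[0] if len(self.at_risk) else 0], self.at_risk]),
                "events": np.concatenate([[0], self.events]),
            }
        )


@dataclass
class StratificationResult:
    labels: dict[str, int]
    chi_square: float
    p_value: float
    km_curves: dict[int, KMCurve] = field(default_factory=dict)
    poor_group: int | None = None
    n_comparisons: int = 1


def parse_clinical(table: pd.DataFrame) -> list[SurvivalRecord]:
    """Build survival records from a TCGA-style clinical table.

    Columns: patient_id, vital_status, days_to_death, days_to_last_followup.
    LIVING -> censored at days_to_last_followup; otherwise event at
    days_to_death. Rows whose required day field is missing are excluded (count
    logged).
    """
    required = {"patient_id", "vital_status", "days_to_death", "days_to_last_followup"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    records: list[SurvivalRecord] = []
    n_excluded = 0
    for row in table.itertuples(index=False):
        status = str(row.vital_status).strip().upper()
        if status in ("", "NAN", "NONE"):
            n_excluded += 1
            continue
        raw = row.days_to_last_followup if status == "LIVING" else row.days_to_death
        try:
            time = float(raw)
        except (TypeError, ValueError):
            time = float("nan")
        if not np.isfinite(time):
            n_excluded += 1
            continue
        records.append(
            SurvivalRecord(patient_id=str(row.patient_id), time=time, event=status != "LIVING")
        )
    if n_excluded:
        logger.info("parse_clinical: excluded %d rows with missing fields", n_excluded)
    if not records:
        raise ValueError("no valid clinical rows")
    return records


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    n = len(records)
    surv, at_risk_out, d_out = [], [], []
    s = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        at_risk_out.append(n_at_risk)
        d_out.append(d)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk_out),
        events=np.array(d_out),
    )


def logrank_test(
    records: list[SurvivalRecord], labels: dict[str, int]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p_value).

    At each distinct event time the observed events in group 0 are compared
    with their expectation under the hypergeometric at-risk model;
    chi-square = (sum O - sum E)^2 / sum V with 1 degree of freedom.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    recs = [r for r in records if r.patient_id in labels]
    if not recs:
        raise ValueError("no records match the label map")
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])
    in0 = np.array([labels[r.patient_id] == groups[0] for r in recs])
    if not in0.any() or in0.all():
        raise ValueError("both groups must be non-empty")
    if not events.any():
        raise ValueError("log-rank undefined: no events in either group")
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n0 = int((at_risk & in0).sum())
        dead = (times == t) & events
        d = int(dead.sum())
        d0 = int((dead & in0).sum())
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1.0 - n0 / n) * (n - d) / (n - 1)
    if V == 0.0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def kmeans_two_groups(
    expr: pd.DataFrame,
    repeats: int = 100,
    seed: int = 0,
) -> dict[str, int]:
    """Cluster patients into two groups by K-means under correlation distance.

    ``expr`` is patients (rows) x module genes (columns). Each patient vector
    is standardized to zero mean and unit norm across genes, after which
    squared Euclidean distance is monotone in 1 - correlation; K-means (k=2) is
    run ``repeats`` times from seeded random initializations and the solution
    with minimal within-cluster dispersion is kept. Labels are canonicalized so
    the group containing the lexicographically smallest patient id is 0.
    """
    if expr.shape[0] < 4:
        raise ValueError(f"need >= 4 patients, got {expr.shape[0]}")
    if expr.shape[1] < 2:
        raise ValueError(f"need >= 2 genes, got {expr.shape[1]}")
    X = expr.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    flat = np.where(norms == 0)[0]
    if len(flat):
        raise ValueError(
            f"constant expression vector for patient(s): "
            f"{[str(expr.index[i]) for i in flat[:5]]}"
        )
    X = X / norms[:, None]
    km = KMeans(
        n_clusters=2,
        n_init=repeats,
        init="random",
        random_state=int(seed) % 2**31,
    )
    raw = km.fit_predict(X)
    patients = [str(p) for p in expr.index]
    anchor = raw[patients.index(min(patients))]
    labels = {p: int(l != anchor) for p, l in zip(patients, raw)}
    return labels


def stratify_and_test(
    expr,
    module_genes,
    clinical: list[SurvivalRecord],
    repeats: int = 100,
    seed: int = 0,
    bonferroni: int | None = None,
) -> StratificationResult:
    """Full stratification: restrict to module genes, cluster, log-rank, KM curves.

    ``expr`` is an ExpressionDataset or a genes x patients DataFrame; only the
    module genes present in the matrix are used. ``bonferroni`` multiplies the
    p-value by the declared number of comparisons (capped at 1).
    """
    frame = expr.to_frame() if hasattr(expr, "to_frame") and not isinstance(expr, pd.DataFrame) else pd.DataFrame(expr)
    matched = sorted(set(module_genes) & set(map(str, frame.index)))
    if not matched:
        raise ValueError("no module genes matched in the expression matrix")
    logger.info("stratify_and_test: %d/%d module genes matched", len(matched), len(set(module_genes)))
    patients_expr = frame.loc[matched].T  # patients x genes
    clinical_ids = {r.patient_id for r in clinical}
    keep = [p for p in patients_expr.index if str(p) in clinical_ids]
    if len(keep) < 4:
        raise ValueError("fewer than 4 patients with both expression and clinical data")
    labels = kmeans_two_groups(patients_expr.loc[keep], repeats=repeats, seed=seed)
    recs = [r for r in clinical if r.patient_id in labels]
    chi2, p = logrank_test(recs, labels)
    n_comp = int(bonferroni) if bonferroni else 1
    p_adj = min(1.0, p * n_comp)
    curves: dict[int, KMCurve] = {}
    rms: dict[int, float] = {}
    for g in (0, 1):
        group_recs = [r for r in recs if labels[r.patient_id] == g]
        curve = km_estimate(group_recs)
        curves[g] = curve
        # restricted mean survival over the observed horizon, for good/poor naming
        horizon = max(r.time for r in recs)
        breaks = np.concatenate([[0.0], curve.times, [horizon]])
        step_vals = np.concatenate([[1.0], curve.survival])  # S on [breaks[i], breaks[i+1])
        widths = np.clip(np.diff(breaks), 0.0, None)
        rms[g] = float(np.sum(widths * step_vals))
    poor = 0 if rms[0] < rms[1] else 1
    return StratificationResult(
        labels=labels,
        chi_square=chi2,
        p_value=p_adj,
        km_curves=curves,
        poor_group=poor,
        n_comparisons=n_comp,
    )
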