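"""Performance metrics, cross-validation protocols and statistical tests.

Agreement between predicted and experimental ddG is summarized by the
Pearson correlation R, the RMSE of the residuals and the regression slope.
Classification of highly destabilizing (ddG >= +1 kcal/mol) or highly
stabilizing (ddG <= -1 kcal/mol) mutations is assessed with ROC curves,
trapezoid AUC and the maximal Matthews correlation coefficient over the
threshold sweep.

Five cross-validation schemes are provided.  CV1/CV2 are repeated random
80/20 and 50/50 splits; CV3 first subsamples up to a fixed number of
mutations per protein to damp the influence of heavily measured proteins;
CV4 leaves one protein out per fold; CV5 leaves out a whole cluster of
similar proteins (>25% sequence identity).  In every scheme a forward
mutation and its reverse partner always land on the same side of the split,
so a model can never see the mirror image of a test mutation during
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .datasets import MutationDataset, ProteinCluster
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    SchemaError,
    ValidationError,
)
from .model import StabilityForest

EXTREME_DDG = 1.0  # kcal/mol threshold for "highly (de)stabilizing"


# ---------------------------------------------------------------------------
# scalar metrics

def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise SchemaError("length mismatch")
    if len(x) < 3:
        raise ValidationError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def rmse(experimental, predicted) -> float:
    a = np.asarray(experimental, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if len(a) != len(b):
        raise SchemaError("length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def fit_slope(experimental, predicted) -> float:
    """Least-squares slope of predicted regressed on experimental values."""
    x = np.asarray(experimental, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("slope undefined for constant experimental values")
    return float(np.polyfit(x, y, 1)[0])


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    for v in (tp, tn, fp, fn):
        if v < 0 or int(v) != v:
            raise ValidationError("confusion-matrix counts must be non-negative integers")
    if tp + tn + fp + fn == 0:
        raise DegenerateInputError("empty confusion matrix")
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    return float(num / np.sqrt(np.prod([float(f) for f in denom_factors])))


# ---------------------------------------------------------------------------
# ROC

@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    max_mcc: float
    max_mcc_threshold: float


def roc_analysis(scores, labels) -> RocResult:
    """ROC over a sweep of all unique score thresholds (positive iff
    score >= threshold), trapezoid AUC, and the maximal MCC over the sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise SchemaError("length mismatch")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both classes present")

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    # cumulative counts at each unique threshold (predict positive if >= t)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(l)[distinct]
    fp = np.cumsum(~l)[distinct]
    thresholds = s[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))

    best_mcc, best_thr = -2.0, float("nan")
    for t, f, thr in zip(tp, fp, thresholds):
        m = mcc(int(t), n_neg - int(f), int(f), n_pos - int(t))
        if m > best_mcc:
            best_mcc, best_thr = m, float(thr)
    return RocResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr,
        auc=auc, max_mcc=best_mcc, max_mcc_threshold=best_thr,
    )


def label_extremes(ddg_exp) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels for highly destabilizing (>= +1.0, inclusive) and highly
    stabilizing (<= -1.0, inclusive) mutations."""
    ddg = np.asarray(ddg_exp, dtype=float)
    if not np.all(np.isfinite(ddg)):
        raise ValidationError("ddG values must be finite")
    return ddg >= EXTREME_DDG, ddg <= -EXTREME_DDG


def antisymmetry_audit(pred_forward, pred_reverse) -> tuple[float, float]:
    """(R_FR, mean bias) over paired forward/reverse predictions.

    R_FR is the Pearson correlation between the two arrays (-1 for a
    perfectly anti-symmetric predictor); the bias is mean(pred_F + pred_R),
    zero when predictions mirror exactly.
    """
    pf = np.asarray(pred_forward, dtype=float)
    pr = np.asarray(pred_reverse, dtype=float)
    if pf.shape != pr.shape:
        raise SchemaError("forward/reverse arrays must have identical shape")
    return pearson_r(pf, pr), float(np.mean(pf + pr))


# ---------------------------------------------------------------------------
# statistical comparisons

def compare_correlations_independent(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p-value for the difference of two correlations measured on
    independent groups (Fisher z-transform test)."""
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValidationError("correlations must be strictly inside (-1, 1)")
    for n in (n1, n2):
        if n < 4:
            raise ValidationError("need n >= 4 in each group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class DelongResult:
    p_value: float
    auc_a: float
    auc_b: float
    z: float


def _midrank_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (AUC, per-positive V10, per-negative V01)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    tz = stats.rankdata(np.r_[pos, neg], method="average")
    tx = stats.rankdata(pos, method="average")
    ty = stats.rankdata(neg, method="average")
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_auc_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong's test for two correlated ROC curves measured on the same cases.

    Returns the two-sided p-value and both trapezoid-equivalent AUCs (the
    Mann-Whitney statistic).  Identical score vectors give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (len(a) == len(b) == len(labels)):
        raise SchemaError("scores and labels must be paired, equal-length arrays")
    if labels.all() or not labels.any():
        raise DegenerateInputError("DeLong test needs both classes present")

    auc_a, v10_a, v01_a = _midrank_components(a, labels)
    auc_b, v10_b, v01_b = _midrank_components(b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return DelongResult(p_value=1.0, auc_a=float(auc_a), auc_b=float(auc_b), z=0.0)
    z = (auc_a - auc_b) / np.sqrt(var)
    return DelongResult(
        p_value=float(2 * stats.norm.sf(abs(z))),
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        z=float(z),
    )


# ---------------------------------------------------------------------------
# evaluation reports

@dataclass
class EvaluationReport:
    r: float
    rmse: float
    slope: float
    n: int
    strata: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"r": self.r, "rmse": self.rmse, "slope": self.slope, "n": self.n,
                "strata": self.strata}


def evaluate_predictions(
    experimental, predicted, strata: dict[str, Sequence] | None = None
) -> EvaluationReport:
    """Summarize agreement, optionally broken down by named strata (each a
    per-sample label array, e.g. forward/reverse or COR/SUR)."""
    x = np.asarray(experimental, dtype=float)
    y = np.asarray(predicted, dtype=float)
    report = EvaluationReport(
        r=pearson_r(x, y), rmse=rmse(x, y), slope=fit_slope(x, y), n=len(x)
    )
    if strata:
        for name, labels in strata.items():
            labels = np.asarray(labels)
            for value in np.unique(labels):
                mask = labels == value
                sub = {"n": int(mask.sum())}
                if mask.sum() >= 3 and np.ptp(x[mask]) > 0 and np.ptp(y[mask]) > 0:
                    sub["r"] = pearson_r(x[mask], y[mask])
                    sub["rmse"] = rmse(x[mask], y[mask])
                report.strata[f"{name}={value}"] = sub
    return report


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CvScheme:
    """Configuration of one cross-validation protocol.

    kind: CV1 (repeated 80/20), CV2 (repeated 50/50), CV3 (per-protein cap
    then 80/20), CV4 (leave-one-protein-out), CV5 (leave-one-cluster-out).
    """

    kind: str
    repeats: int = 100
    fraction: float | None = None
    cap: int = 20
    seed: int = 0

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in ("CV1", "CV2", "CV3", "CV4", "CV5"):
            raise ConfigurationError(f"unknown CV kind {self.kind!r}")
        if self.fraction is None:
            self.fraction = {"CV1": 0.8, "CV2": 0.5, "CV3": 0.8}.get(self.kind)
        if self.kind in ("CV1", "CV2", "CV3") and not 0 < self.fraction < 1:
            raise ConfigurationError("training fraction must be in (0, 1)")
        if self.kind == "CV3" and self.cap < 1:
            raise ConfigurationError("per-protein cap must be >= 1")


def _units(dataset: MutationDataset) -> list[tuple[str, list[int]]]:
    """Indivisible sampling units: a forward/reverse pair moves together.

    Returns (protein_id, record indices) per unit, ordered deterministically.
    """
    by_pair: dict = {}
    order: list = []
    for i, rec in enumerate(dataset.records):
        key = ("pair", rec.protein_id, rec.pair_id) if rec.pair_id is not None else ("single", i)
        if key not in by_pair:
            by_pair[key] = (rec.protein_id, [])
            order.append(key)
        by_pair[key][1].append(i)
    return [by_pair[k] for k in order]


def generate_cv_splits(
    dataset: MutationDataset,
    scheme: CvScheme,
    clusters: Sequence[ProteinCluster] | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_indices, test_indices) per round, pair-aware.

    CV4 yields one fold per protein, CV5 one per protein cluster; the random
    schemes derive all randomness from ``scheme.seed``.
    """
    units = _units(dataset)
    rng = np.random.default_rng(scheme.seed)

    def emit(train_units, test_units):
        train = np.array(sorted(i for _, idx in train_units for i in idx), dtype=int)
        test = np.array(sorted(i for _, idx in test_units for i in idx), dtype=int)
        return train, test

    if scheme.kind in ("CV1", "CV2"):
        for _ in range(scheme.repeats):
            perm = rng.permutation(len(units))
            n_train = int(round(scheme.fraction * len(units)))
            n_train = min(max(n_train, 1), len(units) - 1)
            train_units = [units[i] for i in perm[:n_train]]
            test_units = [units[i] for i in perm[n_train:]]
            yield emit(train_units, test_units)
    elif scheme.kind == "CV3":
        proteins: dict[str, list] = {}
        for u in units:
            proteins.setdefault(u[0], []).append(u)
        for _ in range(scheme.repeats):
            subset = []
            for pid in sorted(proteins):
                group = proteins[pid]
                budget = scheme.cap
                for j in rng.permutation(len(group)):
                    unit = group[j]
                    if len(unit[1]) <= budget:
                        subset.append(unit)
                        budget -= len(unit[1])
                    if budget == 0:
                        break
            perm = rng.permutation(len(subset))
            n_train = int(round(scheme.fraction * len(subset)))
            n_train = min(max(n_train, 1), len(subset) - 1)
            yield emit([subset[i] for i in perm[:n_train]],
                       [subset[i] for i in perm[n_train:]])
    elif scheme.kind == "CV4":
        for pid in sorted({u[0] for u in units}):
            test_units = [u for u in units if u[0] == pid]
            train_units = [u for u in units if u[0] != pid]
            yield emit(train_units, test_units)
    else:  # CV5
        if clusters is None:
            raise ConfigurationError("CV5 requires protein cluster assignments")
        covered = {m for c in clusters for m in c.members}
        ds_proteins = set(dataset.proteins())
        if not ds_proteins <= covered:
            raise ConfigurationError(
                f"clusters do not cover proteins: {sorted(ds_proteins - covered)}"
            )
        for cluster in sorted(clusters, key=lambda c: c.cluster_id):
            members = set(cluster.members) & ds_proteins
            if not members:
                continue
            test_units = [u for u in units if u[0] in members]
            train_units = [u for u in units if u[0] not in members]
            yield emit(train_units, test_units)


@dataclass
class CvResult:
    scheme: CvScheme
    reports: list[EvaluationReport]
    summary: dict[str, float]
    seeds: list[int]


def run_cv(
    dataset: MutationDataset,
    X,
    scheme: CvScheme,
    model_params: dict | None = None,
    clusters: Sequence[ProteinCluster] | None = None,
    locations: Sequence[str] | None = None,
) -> CvResult:
    """Train/test the forest under one CV protocol.

    ``X`` is the feature matrix aligned row-by-row with ``dataset.records``.
    Per-round model seeds are spawned from ``scheme.seed`` and logged.
    Returns per-round reports plus summary means and the pooled R_FR over all
    held-out forward/reverse prediction pairs.
    """
    X = np.asarray(X, dtype=float)
    y = dataset.ddg_array()
    if len(X) != len(dataset.records):
        raise SchemaError("feature matrix not aligned with dataset")
    params = dict(model_params or {})
    seed_seq = np.random.SeedSequence(scheme.seed)
    reports: list[EvaluationReport] = []
    seeds: list[int] = []
    pooled_pairs: dict = {}

    directions = np.array([r.direction for r in dataset.records])
    for round_idx, (train_idx, test_idx) in enumerate(
        generate_cv_splits(dataset, scheme, clusters)
    ):
        child = seed_seq.spawn(1)[0]
        round_seed = int(child.generate_state(1)[0] % (2**31))
        seeds.append(round_seed)
        model = StabilityForest(**{**params, "seed": round_seed})
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])

        strata = {"direction": directions[test_idx]}
        signs = np.where(y[test_idx] >= 0, "destabilizing", "stabilizing")
        strata["sign"] = signs
        if locations is not None:
            strata["location"] = np.asarray(locations)[test_idx]
        if np.ptp(y[test_idx]) > 0 and np.ptp(pred) > 0 and len(test_idx) >= 3:
            reports.append(evaluate_predictions(y[test_idx], pred, strata))
        else:
            reports.append(EvaluationReport(float("nan"), rmse(y[test_idx], pred),
                                            float("nan"), len(test_idx)))
        for local_i, global_i in enumerate(test_idx):
            rec = dataset.records[global_i]
            if rec.pair_id is None:
                continue
            slot = pooled_pairs.setdefault((round_idx, rec.protein_id, rec.pair_id), {})
            slot[rec.direction] = float(pred[local_i])

    pf = [v["forward"] for v in pooled_pairs.values() if len(v) == 2]
    pr = [v["reverse"] for v in pooled_pairs.values() if len(v) == 2]
    summary = {
        "mean_r": float(np.nanmean([rep.r for rep in reports])),
        "mean_rmse": float(np.nanmean([rep.rmse for rep in reports])),
        "mean_slope": float(np.nanmean([rep.slope for rep in reports])),
        "rounds": len(reports),
    }
    if len(pf) >= 3:
        r_fr, bias = antisymmetry_audit(pf, pr)
        summary["r_fr"] = r_fr
        summary["antisymmetry_bias"] = bias
    return CvResult(scheme=scheme, reports=reports, summary=summary, seeds=seeds)
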