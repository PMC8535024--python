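"""Paired ROC evaluation: AUC, bootstrap CIs, Youden points, DeLong, McNemar.

The unit of analysis is the lesion. AUC is the Mann-Whitney statistic
(ties counted half), its 95% CI comes from a percentile bootstrap over
lesions (1000 resamples by default), operating points maximize the Youden
index J = sensitivity + specificity - 1, proportion CIs use the Wald
normal approximation (z = 1.96), paired AUCs are compared with the fast
DeLong test on midrank structural components, and paired sensitivities /
specificities with McNemar's test (exact binomial for fewer than 25
discordant pairs, chi-square with continuity correction otherwise).
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = ["auc", "bootstrap_auc_ci", "youden_point", "wald_ci", "delong_test",
           "mcnemar_test", "evaluate", "roc_result", "ROCResult", "RateCI",
           "PairedComparison", "GroupResult", "EvalReport", "default_groups"]

Z95 = 1.96


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: (#{pos > neg} + 0.5 #{pos = neg}) / (n_pos n_neg)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_binary(labels)
    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_auc_ci(scores, labels, n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling lesions.

    Resamples containing a single class are redrawn (they carry no AUC).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_binary(labels)
    rng = np.random.default_rng(seed)
    n = labels.size
    stats = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
        stats[b] = auc(scores[idx], lab)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def youden_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing J = sens + spec - 1 over the observed scores.

    The decision rule is ``score >= threshold``; ties on J are broken by
    higher sensitivity, then by lower threshold. Returns
    (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_binary(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for t in np.unique(scores):
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        key = (sens + spec - 1, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return float(best[1]), best[2], best[3]


def wald_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Wald 95% interval p +- 1.96 sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must lie in [0, 1]")
    half = Z95 * np.sqrt(p_hat * (1 - p_hat) / n)
    return float(max(p_hat - half, 0.0)), float(min(p_hat + half, 1.0))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank structural components (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    aucv = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n          # per positive lesion
    v01 = 1.0 - (tz[m:] - ty) / m    # per negative lesion
    return float(aucv), v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (delta_auc, two-sided p). Identical score vectors give
    (0, 1) by convention.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = _check_binary(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("scores must be paired on identical lesions")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    delta = auc_a - auc_b
    var = 0.0
    # a class with a single lesion contributes no estimable variance
    if m >= 2:
        s10 = np.cov(np.vstack([v10_a, v10_b]))
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n >= 2:
        s01 = np.cov(np.vstack([v01_a, v01_b]))
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else float("nan")
    z = delta / np.sqrt(var)
    return float(delta), float(2 * norm.sf(abs(z)))


def mcnemar_test(correct_a, correct_b) -> float:
    """Two-sided McNemar p for paired correctness indicators.

    Exact binomial when the discordant count b + c < 25, chi-square with
    continuity correction otherwise; b + c = 0 gives p = 1 by convention.
    """
    a = np.asarray(correct_a).astype(bool)
    b = np.asarray(correct_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must be paired (equal length)")
    n01 = int((a & ~b).sum())
    n10 = int((~a & b).sum())
    if n01 + n10 == 0:
        return 1.0
    table = [[int((a & b).sum()), n01], [n10, int((~a & ~b).sum())]]
    exact = (n01 + n10) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# report containers


@dataclass
class RateCI:
    value: float | None
    lo: float | None = None
    hi: float | None = None

    @classmethod
    def from_count(cls, k: int, n: int) -> "RateCI":
        if n == 0:
            return cls(None)
        p = k / n
        lo, hi = wald_ci(p, n)
        return cls(float(p), lo, hi)


@dataclass
class ROCResult:
    """Per-model, per-group ROC summary at a Youden operating point."""

    n_pos: int
    n_neg: int
    evaluable: bool
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    threshold: float | None = None
    sensitivity: RateCI = field(default_factory=lambda: RateCI(None))
    specificity: RateCI = field(default_factory=lambda: RateCI(None))
    ppv: RateCI = field(default_factory=lambda: RateCI(None))
    npv: RateCI = field(default_factory=lambda: RateCI(None))


@dataclass
class PairedComparison:
    """Model-vs-baseline paired tests within one group."""

    baseline: str
    delta_auc: float | None = None
    p_delong: float | None = None
    p_mcnemar_sensitivity: float | None = None
    p_mcnemar_specificity: float | None = None
    discordant_sensitivity: tuple[int, int] | None = None
    discordant_specificity: tuple[int, int] | None = None


@dataclass
class GroupResult:
    n: int
    n_pos: int
    n_neg: int
    models: dict
    comparisons: dict


@dataclass
class EvalReport:
    groups: dict

    def to_dict(self) -> dict:
        return {name: asdict(g) for name, g in self.groups.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gname, g in self.groups.items():
            for mname, r in g.models.items():
                rows.append({
                    "group": gname, "model": mname, "n": g.n,
                    "n_pos": r.n_pos, "n_neg": r.n_neg,
                    "auc": r.auc,
                    "auc_lo": r.auc_ci[0] if r.auc_ci else None,
                    "auc_hi": r.auc_ci[1] if r.auc_ci else None,
                    "threshold": r.threshold,
                    "sensitivity": r.sensitivity.value,
                    "specificity": r.specificity.value,
                    "ppv": r.ppv.value, "npv": r.npv.value,
                })
        return pd.DataFrame(rows)


def roc_result(scores, labels, n_boot: int = 1000, seed: int = 0,
               threshold: float | None = None) -> ROCResult:
    """Full ROC summary; groups with a single class are flagged not-evaluable."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return ROCResult(n_pos, n_neg, evaluable=False)
    aucv = auc(scores, labels)
    ci = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    if threshold is None:
        threshold, _, _ = youden_point(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    return ROCResult(
        n_pos, n_neg, True, aucv, ci, float(threshold),
        sensitivity=RateCI.from_count(tp, tp + fn),
        specificity=RateCI.from_count(tn, tn + fp),
        ppv=RateCI.from_count(tp, tp + fp),
        npv=RateCI.from_count(tn, tn + fn),
    )


def roc_curve_frame(scores, labels) -> pd.DataFrame:
    """(fpr, tpr, threshold) table of the empirical ROC curve."""
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int),
                              np.asarray(scores, dtype=np.float64))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def default_groups(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Standard subgroup masks: all, zones, focality, PI-RADS, index x PSA."""
    groups = {"all": np.ones(len(records), dtype=bool)}
    for zone in ("PZ", "TZ"):
        groups[f"zone_{zone}"] = (records["zone"] == zone).to_numpy()
    for focality in ("solitary", "multifocal"):
        groups[f"focality_{focality}"] = (records["focality"] == focality).to_numpy()
    for score in (3, 4, 5):
        groups[f"pirads_{score}"] = (records["pirads"] == score).to_numpy()
    if "is_index" in records:
        index = records["is_index"].astype(bool).to_numpy()
        psa = records["psa"].to_numpy()
        groups["index_all"] = index
        groups["index_psa_lt4"] = index & (psa < 4)
        groups["index_psa_4_10"] = index & (psa >= 4) & (psa < 10)
        groups["index_psa_ge10"] = index & (psa >= 10)
    return groups


def evaluate(predictions: dict[str, np.ndarray], records: pd.DataFrame,
             baseline: str = "pirads_cla", groups: dict[str, np.ndarray] | None = None,
             n_boot: int = 1000, seed: int = 0,
             thresholds: dict[str, float] | None = None) -> EvalReport:
    """Per-group ROC summaries plus paired comparisons against a baseline.

    ``predictions`` maps model name to scores aligned with ``records``.
    Operating thresholds are selected by the Youden index on the full set
    (group ``all``) and reused within subgroups, unless ``thresholds``
    supplies externally chosen cutoffs (e.g. from a validation split).
    Groups with a single class are reported as not-evaluable; empty groups
    are skipped.
    """
    labels = records["label"].to_numpy().astype(int)
    if groups is None:
        groups = default_groups(records)
    thresholds = dict(thresholds or {})
    for name, scores in predictions.items():
        if len(scores) != len(records):
            raise ValueError(f"predictions for {name!r} are not aligned with records")
        if name not in thresholds:
            thresholds[name], _, _ = youden_point(scores, labels)
    hard = {name: np.asarray(scores) >= thresholds[name]
            for name, scores in predictions.items()}

    out = {}
    for gname, mask in groups.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            continue
        glabels = labels[mask]
        models = {}
        for mi, (name, scores) in enumerate(predictions.items()):
            models[name] = roc_result(np.asarray(scores)[mask], glabels,
                                      n_boot=n_boot, seed=seed + mi,
                                      threshold=thresholds[name])
        comparisons = {}
        if baseline in predictions and glabels.min() != glabels.max():
            base_scores = np.asarray(predictions[baseline])[mask]
            base_hard = hard[baseline][mask]
            for name, scores in predictions.items():
                if name == baseline:
                    continue
                delta, p = delong_test(np.asarray(scores)[mask], base_scores, glabels)
                comp = PairedComparison(baseline=baseline, delta_auc=delta, p_delong=p)
                pos = glabels == 1
                neg = ~pos
                ca, cb = hard[name][mask][pos], base_hard[pos]
                comp.p_mcnemar_sensitivity = mcnemar_test(ca, cb)
                comp.discordant_sensitivity = (int((ca & ~cb).sum()), int((~ca & cb).sum()))
                ca, cb = ~hard[name][mask][neg], ~base_hard[neg]
                comp.p_mcnemar_specificity = mcnemar_test(ca, cb)
                comp.discordant_specificity = (int((ca & ~cb).sum()), int((~ca & cb).sum()))
                comparisons[name] = comp
        out[gname] = GroupResult(int(mask.sum()), int((glabels == 1).sum()),
                                 int((glabels == 0).sum()), models, comparisons)
    return EvalReport(out)
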