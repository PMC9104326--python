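"""Benchmark statistics for residue-wise disorder predictors.

Confusion-matrix metrics (MCC, F1), ROC/AUC and precision-recall/Fmax
curves (scikit-learn), per-protein RMSD between label vectors, disorder
content and protein-class binning, reproducible bootstrap summaries, and
cross-predictor correlation of per-protein RMSD.

Positive class throughout is *disordered* (label 1), and every metric is
computed on evaluated (unmasked) residues only.  Metrics that are
mathematically undefined on the given input (single-class reference,
empty vectors) return ``None`` rather than an arbitrary number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CurveResult:
    """An ROC or precision-recall curve plus its scalar summary."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    summary: float
    kind: str = "roc"           # {"roc", "pr"}


@dataclass
class BootstrapSummary:
    mean: float
    stderr: float
    n_samples: int
    sample_size: int
    seed: int


@dataclass
class EvaluationReport:
    """Per-predictor benchmark metrics on one reference dataset."""

    predictor: str
    dataset: str
    auc: float | None = None
    fmax: float | None = None
    mcc: float | None = None
    rmsd_mean: float | None = None
    rmsd_by_class: dict = field(default_factory=dict)
    rmsd_per_protein: dict = field(default_factory=dict)
    disorder_content_pred: list = field(default_factory=list)
    disorder_content_ref: list = field(default_factory=list)
    n_residues: int = 0
    n_proteins: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "dataset": self.dataset,
            "auc": self.auc,
            "fmax": self.fmax,
            "mcc": self.mcc,
            "rmsd_mean": self.rmsd_mean,
            "rmsd_by_class": self.rmsd_by_class,
            "n_residues": self.n_residues,
            "n_proteins": self.n_proteins,
            **self.extras,
        }


# ---------------------------------------------------------------------------
# confusion-matrix metrics


def confusion(reference, prediction, mask=None) -> ConfusionCounts:
    """Confusion counts with disordered (1) as the positive class.

    ``mask`` marks residues to exclude (True = masked).
    """
    ref = np.asarray(reference, dtype=int)
    pred = np.asarray(prediction, dtype=int)
    if ref.shape != pred.shape:
        raise ValueError("reference/prediction length mismatch")
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        ref, pred = ref[keep], pred[keep]
    return ConfusionCounts(
        tp=int(((ref == 1) & (pred == 1)).sum()),
        fp=int(((ref == 0) & (pred == 1)).sum()),
        tn=int(((ref == 0) & (pred == 0)).sum()),
        fn=int(((ref == 1) & (pred == 0)).sum()))


def mcc(counts: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient in [-1, 1].

    Returns ``None`` (undefined) when the reference holds a single
    class; returns 0.0 when both classes are present but a denominator
    factor vanishes (the standard convention).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    pos, neg = tp + fn, tn + fp
    if pos == 0 or neg == 0:
        return None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def f1_from_counts(counts: ConfusionCounts) -> float | None:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fn == 0:
        return None
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


# ---------------------------------------------------------------------------
# threshold-free curves


def _check_two_class(ref):
    return 0 < ref.sum() < len(ref)


def roc_auc(reference, scores, mask=None) -> CurveResult | None:
    """ROC curve and trapezoidal AUC; higher score = more disordered.

    The AUC equals the probability that a random disordered residue
    outscores a random ordered one, with ties counted one half.  Returns
    ``None`` on a single-class reference.
    """
    ref = np.asarray(reference, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        ref, sc = ref[keep], sc[keep]
    if len(ref) == 0 or not _check_two_class(ref):
        return None
    fpr, tpr, thr = skm.roc_curve(ref, sc)
    return CurveResult(x=fpr, y=tpr, thresholds=thr,
                       summary=float(skm.auc(fpr, tpr)), kind="roc")


def pr_fmax(reference, scores, mask=None) -> CurveResult | None:
    """Precision-recall curve and Fmax over all score thresholds."""
    ref = np.asarray(reference, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        ref, sc = ref[keep], sc[keep]
    if len(ref) == 0 or ref.sum() == 0:
        return None
    precision, recall, thr = skm.precision_recall_curve(ref, sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1 = np.nan_to_num(f1, nan=0.0)
    return CurveResult(x=recall, y=precision, thresholds=thr,
                       summary=float(f1.max()), kind="pr")


# ---------------------------------------------------------------------------
# vector-level statistics


def residue_rmsd(v, w, mask=None) -> float | None:
    """Root-mean-square deviation between two per-residue vectors.

    sqrt(mean_i (v_i - w_i)^2) over evaluated residues; ``None`` when no
    residues remain after masking.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("vector length mismatch")
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        v, w = v[keep], w[keep]
    if len(v) == 0:
        return None
    return float(np.sqrt(np.mean((v - w) ** 2)))


def disorder_content(labels, mask=None) -> float:
    """Fraction of evaluated residues labelled disordered."""
    labels = np.asarray(labels, dtype=int)
    if mask is not None:
        labels = labels[~np.asarray(mask, dtype=bool)]
    if len(labels) == 0:
        raise ValueError("no evaluated residues")
    return float(labels.mean())


def protein_class(content: float, high_cut: float = 0.90,
                  low_cut: float = 0.10) -> str:
    """Bin a protein by disorder content (strict inequalities)."""
    if not 0 <= content <= 1:
        raise ValueError("content outside [0, 1]")
    if content > high_cut:
        return "highly_disordered"
    if content < low_cut:
        return "highly_ordered"
    return "other"


def bootstrap_summary(values, n_samples: int = 10_000,
                      sample_size: int = 60,
                      seed: int = 0) -> BootstrapSummary:
    """Bootstrap mean and its standard error by resampling with replacement.

    Defaults follow protein-level resampling (10,000 samples of size 60);
    residue-level analyses use sample_size 500.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_samples, sample_size))
    means = values[idx].mean(axis=1)
    return BootstrapSummary(mean=float(means.mean()),
                            stderr=float(means.std(ddof=0)),
                            n_samples=n_samples, sample_size=sample_size,
                            seed=seed)


def predictor_correlation(rmsd_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r and least-squares fit between predictors.

    ``rmsd_table``: proteins x predictors of per-protein RMSD values.
    Pairs sharing fewer than 3 proteins yield ``None`` entries.
    """
    cols = list(rmsd_table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = rmsd_table[[a, b]].dropna()
            if len(sub) < 3:
                rows.append((a, b, None, None, None, len(sub)))
                continue
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((a, b, None, None, None, len(sub)))
                continue
            res = stats.linregress(x, y)
            rows.append((a, b, float(res.rvalue), float(res.slope),
                         float(res.intercept), len(sub)))
    return pd.DataFrame(
        rows, columns=["predictor_a", "predictor_b", "pearson_r", "slope",
                       "intercept", "n_proteins"])


# ---------------------------------------------------------------------------
# report assembly


def evaluate_predictor(references: dict, profiles: dict, predictor: str,
                       dataset: str = "",
                       class_high_cut: float = 0.90,
                       class_low_cut: float = 0.10) -> EvaluationReport:
    """Full benchmark of one predictor against a reference set.

    Pooled-residue AUC/Fmax/MCC plus per-protein RMSD (binary calls, or
    continuous scores against binary labels) and disorder content.
    Proteins with zero evaluated residues are skipped.
    """
    ref_all, score_all, call_all = [], [], []
    rmsd_per_protein: dict[str, float] = {}
    rmsd_by_class: dict[str, list] = {}
    content_pred, content_ref = [], []

    for acc, ref in references.items():
        prof = profiles.get(acc)
        if prof is None:
            continue
        if len(prof) != len(ref):
            raise ValueError(f"{acc}: profile/reference length mismatch")
        if ref.n_evaluated == 0:
            continue
        keep = ref.evaluated
        labels = ref.labels[keep]
        values = (prof.scores if prof.scores is not None
                  else prof.calls)[keep]
        ref_all.append(labels)
        if prof.scores is not None:
            score_all.append(prof.scores[keep])
        if prof.calls is not None:
            call_all.append(prof.calls[keep])
        r = residue_rmsd(labels, values)
        rmsd_per_protein[acc] = r
        cls = protein_class(float(labels.mean()), class_high_cut,
                            class_low_cut)
        rmsd_by_class.setdefault(cls, []).append(r)
        content_ref.append(float(labels.mean()))
        if prof.calls is not None:
            content_pred.append(float(prof.calls[keep].mean()))
        else:
            content_pred.append(float((prof.scores[keep] >= 0.5).mean()))

    if not ref_all:
        raise ValueError("no proteins with evaluated residues")
    ref_pool = np.concatenate(ref_all)

    report = EvaluationReport(predictor=predictor, dataset=dataset,
                              n_residues=len(ref_pool),
                              n_proteins=len(rmsd_per_protein))
    if score_all:
        pool = np.concatenate(score_all)
        roc = roc_auc(ref_pool, pool)
        pr = pr_fmax(ref_pool, pool)
        report.auc = None if roc is None else roc.summary
        report.fmax = None if pr is None else pr.summary
    if call_all:
        pool = np.concatenate(call_all)
        report.mcc = mcc(confusion(ref_pool, pool))
        roc = roc_auc(ref_pool, pool.astype(float))
        pr = pr_fmax(ref_pool, pool.astype(float))
        if report.auc is None:
            report.auc = None if roc is None else roc.summary
        if report.fmax is None:
            report.fmax = None if pr is None else pr.summary
    report.rmsd_per_protein = rmsd_per_protein
    report.rmsd_mean = float(np.mean(list(rmsd_per_protein.values())))
    report.rmsd_by_class = {k: float(np.mean(v))
                            for k, v in rmsd_by_class.items()}
    report.disorder_content_pred = content_pred
    report.disorder_content_ref = content_ref
    return report
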