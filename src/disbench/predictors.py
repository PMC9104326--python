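"""Structure-derived disorder predictors.

Three predictors are read straight off a predicted structure:

* **DSSPp** — the naive secondary-structure rule: residues in helices,
  strands or H-bond-stabilised turns (DSSP classes H, G, I, E, B, T) are
  ordered; bend 'S' and loop '-' are disordered.
* **tpLD** — the continuous confidence transform ``1 - pLDDT/100``,
  a disorder score in [0, 1] (1 = disordered).
* **pLDn** — the binary discretisation: pLDDT >= n is ordered (0),
  otherwise disordered (1).  The threshold n is chosen by maximising the
  Matthews correlation coefficient over an integer sweep on a reference
  set, pooling evaluated residues across proteins.

External (sequence-based) predictors enter through CAID prediction files
and are never recomputed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import confusion, mcc
from .reference import ReferenceLabels

ORDERED_SS8 = set("HGIEBT")
DISORDERED_SS8 = set("S-")


@dataclass
class DisorderScoreProfile:
    """Per-residue disorder output of one predictor for one target."""

    accession: str
    source: str
    scores: np.ndarray | None = None   # continuous, [0, 1]
    calls: np.ndarray | None = None    # binary {0, 1}

    def __post_init__(self):
        if self.scores is None and self.calls is None:
            raise ValueError("profile needs scores or calls")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if ((self.scores < 0) | (self.scores > 1)).any():
                raise ValueError("scores outside [0, 1]")
        if self.calls is not None:
            self.calls = np.asarray(self.calls, dtype=np.int8)
            if not np.isin(self.calls, (0, 1)).all():
                raise ValueError("calls outside {0, 1}")

    def __len__(self) -> int:
        return len(self.scores if self.scores is not None else self.calls)


@dataclass
class ThresholdSearchResult:
    best_n: int
    mcc_by_n: pd.DataFrame        # columns: n, mcc
    dataset: str = ""

    def __post_init__(self):
        valid = self.mcc_by_n.dropna(subset=["mcc"])
        if not valid.empty:
            assert math.isclose(
                float(valid.loc[valid.n == self.best_n, "mcc"].iloc[0]),
                float(valid.mcc.max()), rel_tol=0, abs_tol=1e-12)


def dsspp_predict(ss8: str, accession: str = "?") -> DisorderScoreProfile:
    """Binary disorder from the naive secondary-structure rule."""
    unknown = set(ss8) - ORDERED_SS8 - DISORDERED_SS8
    if unknown:
        raise ValueError(f"unknown secondary-structure classes: {unknown}")
    calls = np.fromiter((1 if c in DISORDERED_SS8 else 0 for c in ss8),
                        dtype=np.int8, count=len(ss8))
    return DisorderScoreProfile(accession=accession, source="DSSPp",
                                calls=calls)


def tpld_predict(plddt: np.ndarray,
                 accession: str = "?") -> DisorderScoreProfile:
    """Continuous disorder score 1 - pLDDT/100."""
    plddt = np.asarray(plddt, dtype=float)
    if ((plddt < 0) | (plddt > 100)).any():
        warnings.warn("pLDDT outside [0, 100]; clamping", stacklevel=2)
        plddt = np.clip(plddt, 0.0, 100.0)
    return DisorderScoreProfile(accession=accession, source="tpLD",
                                scores=1.0 - plddt / 100.0)


def pldn_predict(plddt: np.ndarray, n: float,
                 accession: str = "?") -> DisorderScoreProfile:
    """Binary disorder: pLDDT >= n is ordered, anything below disordered."""
    if not 0 <= n <= 100:
        raise ValueError(f"threshold n={n} outside [0, 100]")
    plddt = np.asarray(plddt, dtype=float)
    calls = (plddt < n).astype(np.int8)
    return DisorderScoreProfile(accession=accession, source=f"pLD{n:g}",
                                calls=calls)


def select_threshold_mcc(plddt_profiles: dict[str, np.ndarray],
                         references: dict[str, ReferenceLabels],
                         n_grid=None,
                         dataset: str = "") -> ThresholdSearchResult:
    """Integer threshold sweep maximising MCC on pooled evaluated residues.

    Ties resolve to the smallest n (the most ordered calls at the
    margin).  Raises when the pooled reference contains a single class,
    where MCC is undefined at every threshold.
    """
    if n_grid is None:
        n_grid = range(101)
    plddt_all, label_all = [], []
    for acc, ref in references.items():
        p = np.asarray(plddt_profiles[acc], dtype=float)
        if len(p) != len(ref):
            raise ValueError(f"{acc}: profile/reference length mismatch")
        keep = ref.evaluated
        plddt_all.append(p[keep])
        label_all.append(ref.labels[keep])
    plddt = np.concatenate(plddt_all)
    labels = np.concatenate(label_all)
    if labels.min(initial=1) == labels.max(initial=0):
        raise ValueError("single-class reference: MCC undefined")

    rows = []
    best_n, best_mcc = None, -np.inf
    for n in n_grid:
        calls = (plddt < n).astype(np.int8)
        m = mcc(confusion(labels, calls))
        rows.append((int(n), m))
        if m is not None and m > best_mcc + 1e-15:
            best_mcc, best_n = m, int(n)
    table = pd.DataFrame(rows, columns=["n", "mcc"])
    return ThresholdSearchResult(best_n=best_n, mcc_by_n=table,
                                 dataset=dataset)


def combine_thresholds(thresholds) -> int:
    """Arithmetic mean of dataset-optimal thresholds, rounded half-up."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("no thresholds to combine")
    return int(math.floor(sum(thresholds) / len(thresholds) + 0.5))
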