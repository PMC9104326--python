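"""Confidence vs. local secondary structure.

Per-class pLDDT distributions (with KDE and bootstrap summaries),
secondary-structure codons — the triplet of reduced classes at a residue
and its two neighbours (HHH = helix interior, HHC/CHH = helix ends, and
so on) — per-segment min-max normalisation of confidence (pLDnorm), and
line / power-law fits of normalised confidence against externally
supplied structure propensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

REDUCED_ALPHABET = "HETC"
KDE_GRID_POINTS = 512
LOW_SUPPORT_COUNT = 25
BIMODAL_MIN_SEPARATION = 10.0    # pLDDT units between KDE local maxima


@dataclass
class SSCodon:
    triplet: str
    center_index: int            # 0-based residue position


@dataclass
class ClassDistribution:
    """pLDDT samples for one class or codon, with summary statistics."""

    key: str
    values: np.ndarray
    mean: float = 0.0
    skewness: float = 0.0
    kde_x: np.ndarray | None = None
    kde_y: np.ndarray | None = None
    bootstrap: object = None
    low_support: bool = False

    @property
    def count(self) -> int:
        return len(self.values)

    def fraction_below(self, cutoff: float) -> float:
        return float((self.values < cutoff).mean())

    def fraction_above(self, cutoff: float) -> float:
        return float((self.values > cutoff).mean())

    def kde_peaks(self) -> list[float]:
        """pLDDT positions of local maxima of the KDE curve."""
        if self.kde_y is None or len(self.kde_y) < 3:
            return []
        y = self.kde_y
        idx = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
        return [float(self.kde_x[i]) for i in idx]

    def is_bimodal(self,
                   min_separation: float = BIMODAL_MIN_SEPARATION) -> bool:
        peaks = sorted(self.kde_peaks())
        return any(b - a >= min_separation
                   for a, b in zip(peaks, peaks[1:]))


def codons(reduced_ss: str) -> list[SSCodon]:
    """Secondary-structure codons of a reduced string; termini excluded."""
    if len(reduced_ss) < 3:
        warnings.warn("string shorter than 3 residues: no codons",
                      stacklevel=2)
        return []
    bad = set(reduced_ss) - set(REDUCED_ALPHABET)
    if bad:
        raise ValueError(f"unknown reduced classes: {bad}")
    return [SSCodon(reduced_ss[i - 1:i + 2], i)
            for i in range(1, len(reduced_ss) - 1)]


def _distribution(key: str, values: np.ndarray,
                  bootstrap_spec: tuple[int, int] | None,
                  seed: int) -> ClassDistribution:
    from .evaluation import bootstrap_summary

    values = np.asarray(values, dtype=float)
    dist = ClassDistribution(key=key, values=values,
                             mean=float(values.mean()),
                             skewness=float(stats.skew(values))
                             if len(values) > 2 else 0.0,
                             low_support=len(values) < LOW_SUPPORT_COUNT)
    if len(values) >= 2 and values.std() > 0:
        kde = stats.gaussian_kde(values)            # Scott's rule
        grid = np.linspace(0.0, 100.0, KDE_GRID_POINTS)
        dist.kde_x = grid
        dist.kde_y = kde(grid)
    if bootstrap_spec is not None and len(values) > 0:
        n_samples, sample_size = bootstrap_spec
        dist.bootstrap = bootstrap_summary(values, n_samples, sample_size,
                                           seed=seed)
    return dist


def plddt_by_class(reduced_ss: str, plddt,
                   bootstrap_spec: tuple[int, int] | None = (10_000, 500),
                   seed: int = 0) -> dict[str, ClassDistribution]:
    """Group pLDDT values by reduced secondary-structure class.

    Empty classes are omitted with a warning.  The default bootstrap
    (10,000 resamples of 500 residues) matches residue-level resampling.
    """
    plddt = np.asarray(plddt, dtype=float)
    if len(reduced_ss) != len(plddt):
        raise ValueError("string/profile length mismatch")
    out = {}
    for cls in REDUCED_ALPHABET:
        sel = np.fromiter((c == cls for c in reduced_ss), dtype=bool,
                          count=len(reduced_ss))
        if not sel.any():
            warnings.warn(f"class {cls} empty; omitted", stacklevel=2)
            continue
        out[cls] = _distribution(cls, plddt[sel], bootstrap_spec, seed)
    return out


def plddt_by_codon(codon_list: list[SSCodon], plddt,
                   bootstrap_spec: tuple[int, int] | None = None,
                   seed: int = 0,
                   min_count: int = LOW_SUPPORT_COUNT
                   ) -> dict[str, ClassDistribution]:
    """Group the center-residue pLDDT of each codon by triplet string."""
    plddt = np.asarray(plddt, dtype=float)
    grouped: dict[str, list[float]] = {}
    for codon in codon_list:
        grouped.setdefault(codon.triplet, []).append(
            plddt[codon.center_index])
    out = {}
    for key, vals in grouped.items():
        dist = _distribution(key, np.asarray(vals), bootstrap_spec, seed)
        dist.low_support = len(vals) < min_count
        out[key] = dist
    return out


def pldnorm(plddt_segment) -> np.ndarray:
    """Min-max normalise a contiguous confidence segment to [0, 1]."""
    x = np.asarray(plddt_segment, dtype=float)
    if len(x) < 2:
        raise ValueError("segment shorter than 2 residues")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        warnings.warn("constant segment; pLDnorm set to 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def fit_propensity(pldnorm_values, propensity_values,
                   model: str = "line") -> dict:
    """Fit normalised confidence against per-residue structure propensity.

    ``model="line"``: ordinary least squares y = a + b x.
    ``model="power_law"``: least squares in log-log space, y = a * x^b
    (non-positive points dropped with a warning).  Pearson r is reported
    on the fitted space.
    """
    x = np.asarray(pldnorm_values, dtype=float)
    y = np.asarray(propensity_values, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if model == "line":
        res = stats.linregress(x, y)
        return {"model": "line", "slope": float(res.slope),
                "intercept": float(res.intercept), "r": float(res.rvalue),
                "n": len(x)}
    if model == "power_law":
        keep = (x > 0) & (y > 0)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} non-positive points for "
                "power-law fit", stacklevel=2)
        if keep.sum() < 3:
            raise ValueError("too few positive points for power-law fit")
        res = stats.linregress(np.log(x[keep]), np.log(y[keep]))
        return {"model": "power_law", "a": float(np.exp(res.intercept)),
                "b": float(res.slope), "r": float(res.rvalue),
                "n": int(keep.sum())}
    raise ValueError(f"unknown model: {model}")
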