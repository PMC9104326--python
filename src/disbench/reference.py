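"""Per-residue reference label sets for disorder benchmarking.

Two reference variants are built from 1-based inclusive interval tables:

* **DisProt** — every residue inside a disorder annotation is disordered
  (1); every other residue is ordered (0).  Nothing is masked, so
  unannotated residues silently count as ordered.
* **DisProt-PDB** — only residues with evidence are evaluated: disorder
  annotations give 1 (and win any conflict with structural coverage),
  residues covered by a PDB structure but not annotated give 0, and
  residues with neither are masked and excluded from all metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import intervals_to_mask

logger = logging.getLogger(__name__)

PROV_NONE = "none"
PROV_DISPROT = "disprot"
PROV_PDB = "pdb"


@dataclass
class ReferenceLabels:
    """Ternary per-residue reference: label, evaluation mask, provenance."""

    accession: str
    labels: np.ndarray                  # int8, 0 ordered / 1 disordered
    mask: np.ndarray                    # bool, True = masked (not evaluated)
    provenance: np.ndarray = field(default=None)  # str per residue
    variant: str = "disprot"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.provenance is None:
            self.provenance = np.full(len(self.labels), PROV_NONE,
                                      dtype=object)
        if not (len(self.labels) == len(self.mask) == len(self.provenance)):
            raise ValueError("labels/mask/provenance length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def evaluated(self) -> np.ndarray:
        """Boolean selector of residues that enter metrics."""
        return ~self.mask

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())


def build_disprot_reference(disorder_intervals, length: int,
                            accession: str = "?") -> ReferenceLabels:
    """DisProt variant: annotated residues 1, all others 0, no masking."""
    disordered = intervals_to_mask(disorder_intervals, length, accession)
    prov = np.where(disordered, PROV_DISPROT, PROV_NONE).astype(object)
    return ReferenceLabels(
        accession=accession,
        labels=disordered.astype(np.int8),
        mask=np.zeros(length, dtype=bool),
        provenance=prov,
        variant="disprot")


def build_disprot_pdb_reference(disorder_intervals, coverage_intervals,
                                length: int,
                                accession: str = "?") -> ReferenceLabels:
    """DisProt-PDB variant.

    Disorder annotations label 1 regardless of coverage (annotation-vs-
    structure conflicts resolve to disorder); covered-but-unannotated
    residues label 0; residues with neither source are masked.
    """
    disordered = intervals_to_mask(disorder_intervals, length, accession)
    covered = intervals_to_mask(coverage_intervals, length, accession)
    labels = disordered.astype(np.int8)
    mask = ~(disordered | covered)
    prov = np.full(length, PROV_NONE, dtype=object)
    prov[covered] = PROV_PDB
    prov[disordered] = PROV_DISPROT
    return ReferenceLabels(
        accession=accession, labels=labels, mask=mask, provenance=prov,
        variant="disprot-pdb")


def masked_fraction(references) -> float:
    """Pooled fraction of masked residues over one or many references."""
    if isinstance(references, ReferenceLabels):
        references = [references]
    total = sum(len(r) for r in references)
    if total == 0:
        raise ValueError("no residues")
    masked = sum(int(r.mask.sum()) for r in references)
    return masked / total


def truncate_to_common_length(reference: ReferenceLabels,
                              other_length: int) -> ReferenceLabels:
    """Reconcile a reference with a model of different length.

    The shorter length wins; the event is logged, never fatal.
    """
    n = len(reference)
    if other_length >= n:
        return reference
    logger.warning("%s: truncating reference from %d to %d residues",
                   reference.accession, n, other_length)
    return ReferenceLabels(
        accession=reference.accession,
        labels=reference.labels[:other_length],
        mask=reference.mask[:other_length],
        provenance=reference.provenance[:other_length],
        variant=reference.variant)
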