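"""Readers and writers for every external format the pipeline touches.

Structure models (PDB/mmCIF with per-residue confidence in the B-factor
field), CAID-style per-residue prediction files, DisProt-style interval
tables, and per-residue label/score TSV exports.

Conventions
-----------
* Interval tables are 1-based inclusive on disk; everything in memory is
  0-based.  Conversion happens only here, at the I/O boundary.
* Residue-level confidence (pLDDT, 0-100) is the B-iso of the CA atom,
  falling back to the mean over backbone atoms when CA is absent.
* Only the first model and first alternate location of a structure file
  are read: predicted models carry a single conformer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class EmptyModelError(ValueError):
    """Raised when a structure file contains no residues."""


@dataclass
class AtomRecord:
    """One atom: name, position (Angstrom) and isotropic B (holds pLDDT)."""

    atom_name: str
    x: float
    y: float
    z: float
    b_iso: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ResidueRecord:
    """A residue with its backbone atoms and residue-level confidence."""

    index: int                      # author numbering, 1-based
    name: str                       # 3-letter code
    chain_id: str
    atoms: dict = field(default_factory=dict)   # atom name -> AtomRecord
    plddt: float = float("nan")
    incomplete: bool = False        # missing at least one backbone atom

    def coord(self, atom_name: str) -> np.ndarray | None:
        rec = self.atoms.get(atom_name)
        return None if rec is None else rec.xyz


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)


@dataclass
class StructureModel:
    """Predicted structure: ordered chains of backbone residues + pLDDT."""

    chains: list[Chain] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def residues(self) -> list[ResidueRecord]:
        return [r for c in self.chains for r in c.residues]

    @property
    def plddt(self) -> np.ndarray:
        """Per-residue confidence over all chains, in chain order."""
        return np.concatenate([c.plddt for c in self.chains]) if self.chains \
            else np.empty(0)


@dataclass
class PredictionFile:
    """One predictor's per-residue output for one target (CAID dialect)."""

    accession: str
    positions: np.ndarray           # 1-based, contiguous
    residues: list[str]             # 1-letter codes
    scores: np.ndarray              # [0, 1], higher = more disordered
    labels: np.ndarray | None = None  # optional binary calls


@dataclass
class IntervalAnnotation:
    """1-based inclusive intervals of one kind for one accession."""

    accession: str
    intervals: list[tuple[int, int]]
    kind: str = "disorder"          # {"disorder", "pdb_coverage"}


# ---------------------------------------------------------------------------
# structure files


def _residue_plddt(atoms: dict) -> float:
    ca = atoms.get("CA")
    if ca is not None:
        return ca.b_iso
    vals = [a.b_iso for a in atoms.values()]
    return float(np.mean(vals)) if vals else float("nan")


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF structure; pLDDT is taken from the B-iso field.

    Parameters
    ----------
    path : file in PDB or mmCIF format.
    fmt : "pdb" or "mmcif"; autodetected from the extension when None.

    Residues missing any of N/CA/C/O are kept but flagged ``incomplete``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models")
    model = st[0]

    out = StructureModel(name=st.name or path.stem)
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            atoms: dict[str, AtomRecord] = {}
            for atom in gres:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                if atom.name in atoms:
                    continue
                if not np.isfinite([atom.pos.x, atom.pos.y, atom.pos.z]).all():
                    raise FormatError(f"{path}: non-finite coordinates")
                if not 0.0 <= atom.b_iso <= 100.0:
                    warnings.warn(
                        f"{path}: B-iso {atom.b_iso:.2f} outside [0, 100] "
                        f"at residue {gres.seqid.num}", stacklevel=2)
                atoms[atom.name] = AtomRecord(
                    atom.name, atom.pos.x, atom.pos.y, atom.pos.z, atom.b_iso)
            if not atoms:
                continue
            res = ResidueRecord(
                index=gres.seqid.num, name=gres.name, chain_id=gchain.name,
                atoms=atoms, plddt=_residue_plddt(atoms),
                incomplete=any(a not in atoms for a in BACKBONE_ATOMS))
            chain.residues.append(res)
        if chain.residues:
            idx = [r.index for r in chain.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise FormatError(
                    f"{path}: residue indices not strictly increasing in "
                    f"chain {chain.chain_id}")
            out.chains.append(chain)
    if len(out) == 0:
        raise EmptyModelError(f"{path}: no residues")
    return out


def write_structure(model: StructureModel, path: str | Path,
                    fmt: str = "pdb") -> None:
    """Write a StructureModel as a fixed-column PDB file (B-iso 2 decimals)."""
    if fmt != "pdb":
        raise ValueError(f"unsupported output format: {fmt}")
    if len(model) == 0:
        raise EmptyModelError("refusing to write an empty model")

    st = gemmi.Structure()
    st.name = model.name or "model"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            if res.index > 9999:
                raise OverflowError(
                    f"residue index {res.index} exceeds the PDB field width")
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.index, " ")
            for name in BACKBONE_ATOMS + ("H",):
                rec = res.atoms.get(name)
                if rec is None:
                    continue
                ga = gemmi.Atom()
                ga.name = rec.atom_name
                ga.pos = gemmi.Position(rec.x, rec.y, rec.z)
                ga.b_iso = round(rec.b_iso, 2)
                ga.occ = 1.0
                ga.element = gemmi.Element(rec.atom_name[0])
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# CAID prediction files


def read_caid_predictions(path: str | Path) -> list[PredictionFile]:
    """Parse a CAID-style prediction file.

    The dialect alternates ``>``-prefixed accession headers with
    tab-separated rows ``position  residue  score  [label]``.  Positions
    must be contiguous from 1 and scores in [0, 1]; violations raise a
    :class:`FormatError` naming the accession and line number.
    """
    path = Path(path)
    records: list[PredictionFile] = []
    acc = None
    rows: list[tuple[int, str, float, int | None]] = []

    def _flush():
        if acc is None:
            return
        if not rows:
            raise FormatError(f"{path}: accession {acc} has no rows")
        pos = np.array([r[0] for r in rows], dtype=int)
        labels = [r[3] for r in rows]
        has_labels = all(l is not None for l in labels)
        records.append(PredictionFile(
            accession=acc,
            positions=pos,
            residues=[r[1] for r in rows],
            scores=np.array([r[2] for r in rows], dtype=float),
            labels=np.array(labels, dtype=int) if has_labels else None))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                acc = line[1:].strip().split()[0]
                rows = []
                continue
            if acc is None:
                raise FormatError(f"{path}:{lineno}: data before any header")
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno} ({acc}): expected >=3 tab-separated "
                    f"fields, got {len(parts)}")
            try:
                pos = int(parts[0])
                score = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno} ({acc}): {exc}") from exc
            expected = rows[-1][0] + 1 if rows else 1
            if pos != expected:
                raise FormatError(
                    f"{path}:{lineno} ({acc}): position {pos} not "
                    f"contiguous (expected {expected})")
            if not 0.0 <= score <= 1.0:
                raise FormatError(
                    f"{path}:{lineno} ({acc}): score {score} outside [0, 1]")
            label: int | None = None
            if len(parts) >= 4 and parts[3].strip() != "":
                label = int(parts[3])
                if label not in (0, 1):
                    raise FormatError(
                        f"{path}:{lineno} ({acc}): label {label} not in "
                        "{0, 1}")
            rows.append((pos, parts[1], score, label))
    _flush()
    return records


def write_caid_predictions(records: Iterable[PredictionFile],
                           path: str | Path) -> None:
    """Write prediction records in the CAID text dialect (3-decimal scores)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i, pos in enumerate(rec.positions):
                row = f"{int(pos)}\t{rec.residues[i]}\t{rec.scores[i]:.3f}"
                if rec.labels is not None:
                    row += f"\t{int(rec.labels[i])}"
                fh.write(row + "\n")


# ---------------------------------------------------------------------------
# interval tables


def read_intervals(path: str | Path, kind: str = "disorder"
                   ) -> list[IntervalAnnotation]:
    """Read a TSV of 1-based inclusive intervals: accession, start, end.

    Overlapping intervals are preserved as given; merging is done by the
    reference builder.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["accession", "start", "end"], comment="#",
                     dtype={"accession": str})
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            as_float = pd.to_numeric(df[col], errors="coerce")
            if as_float.isna().any() or (as_float % 1 != 0).any():
                raise FormatError(
                    f"{path}: non-integer interval bound in '{col}'")
            df[col] = as_float.astype(int)
    bad = df[df.start > df.end]
    if not bad.empty:
        row = bad.iloc[0]
        raise FormatError(
            f"{path}: start > end for {row.accession} "
            f"({row.start} > {row.end})")
    if (df.start < 1).any():
        raise FormatError(f"{path}: interval start < 1")
    out = []
    for acc, grp in df.groupby("accession", sort=False):
        out.append(IntervalAnnotation(
            accession=str(acc),
            intervals=[(int(s), int(e)) for s, e in zip(grp.start, grp.end)],
            kind=kind))
    return out


def write_intervals(annotations: Iterable[IntervalAnnotation],
                    path: str | Path) -> None:
    rows = [(a.accession, s, e) for a in annotations for s, e in a.intervals]
    pd.DataFrame(rows, columns=["accession", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# per-residue label/score table


def write_residue_table(path: str | Path, accession: str,
                        reference_labels: Sequence[int],
                        scores: Sequence[float] | None = None,
                        calls: Sequence[int] | None = None,
                        mask: Sequence[bool] | None = None) -> None:
    """Export per-residue reference labels, scores, calls and mask as TSV."""
    n = len(reference_labels)
    df = pd.DataFrame({
        "accession": [accession] * n,
        "position": np.arange(1, n + 1),
        "reference_label": np.asarray(reference_labels, dtype=int),
        "score": np.full(n, np.nan) if scores is None else np.asarray(scores),
        "call": np.full(n, -1) if calls is None else np.asarray(calls),
        "mask": np.zeros(n, dtype=int) if mask is None
                else np.asarray(mask, dtype=int),
    })
    df.to_csv(path, sep="\t", index=False)


def intervals_to_mask(intervals: Sequence[tuple[int, int]], length: int,
                      accession: str = "?") -> np.ndarray:
    """Union of 1-based inclusive intervals as a 0-based boolean array."""
    out = np.zeros(length, dtype=bool)
    for start, end in intervals:
        if start < 1 or end > length:
            raise ValueError(
                f"{accession}: interval ({start}, {end}) outside "
                f"[1, {length}]")
        out[start - 1:end] = True
    return out


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Runs of True in a 0-based boolean array as 1-based inclusive pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s) + 1, int(e)) for s, e in zip(starts, ends)]
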