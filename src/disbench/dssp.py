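"""Kabsch-Sander secondary-structure assignment from backbone geometry.

A from-scratch implementation of the classic 8-class DSSP alphabet
{H, G, I, E, B, T, S, -} driven by the electrostatic hydrogen-bond model

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond recorded when E < -0.5 kcal/mol.  Amide hydrogens are
constructed from the preceding peptide unit (H = N_i + unit(C_{i-1} -
O_{i-1}) * 1.0 A); prolines and chain-start residues donate no hydrogen.

The 4-class reduction used downstream maps H/G/I -> H, E/B -> E, T -> T
and S/'-' -> C.  Bend 'S' and loop '-' are the classes that are *not*
hydrogen-bond stabilised, which is what makes them "disordered" under the
naive structure-based disorder rule.

Numerical choices: pairwise distances are clamped below at 0.5 A inside
the energy formula (malformed input only; real geometry never gets
close), and a peptide-bond C-N distance above 2.5 A is treated as a chain
break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import StructureModel

Q1Q2_F = 27.888          # kcal/mol * A, DSSP electrostatic constant
HBOND_CUTOFF = -0.5      # kcal/mol
MIN_DIST = 0.5           # A, clamp against singular geometry
CHAIN_BREAK_CN = 2.5     # A, peptide C-N distance beyond which chain breaks
BEND_KAPPA = 70.0        # degrees
NH_BOND = 1.0            # A, amide N-H bond length

SS8_ALPHABET = "HGIEBTS-"
_REDUCE = {"H": "H", "G": "H", "I": "H",
           "E": "E", "B": "E",
           "T": "T",
           "S": "C", "-": "C"}


@dataclass
class HydrogenBond:
    donor_residue: int
    acceptor_residue: int
    energy: float


def hbond_energy(n: np.ndarray, h: np.ndarray,
                 c: np.ndarray, o: np.ndarray) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol).

    ``n``/``h`` belong to the donor amide, ``c``/``o`` to the acceptor
    carbonyl.  Distances below 0.5 A are clamped with a warning.
    """
    pts = np.asarray([n, h, c, o], dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    r_on = np.linalg.norm(pts[3] - pts[0])
    r_ch = np.linalg.norm(pts[2] - pts[1])
    r_oh = np.linalg.norm(pts[3] - pts[1])
    r_cn = np.linalg.norm(pts[2] - pts[0])
    d = np.array([r_on, r_ch, r_oh, r_cn])
    if (d < MIN_DIST).any():
        warnings.warn("clamping near-coincident atoms in H-bond energy",
                      stacklevel=2)
        d = np.maximum(d, MIN_DIST)
    return float(Q1Q2_F * (1 / d[0] + 1 / d[1] - 1 / d[2] - 1 / d[3]))


def place_amide_hydrogens(model: StructureModel) -> StructureModel:
    """Attach an ideal amide H to every donor-capable residue, in place.

    H lies 1.0 A from N along the direction of the previous residue's
    C->O bond reversed (the standard DSSP construction).  Prolines,
    chain-start residues and residues following an incomplete peptide
    unit receive no hydrogen and cannot donate.
    """
    from .io_formats import AtomRecord

    for chain in model.chains:
        prev = None
        for res in chain.residues:
            res.atoms.pop("H", None)
            if (prev is not None and res.name != "PRO"
                    and res.coord("N") is not None
                    and prev.coord("C") is not None
                    and prev.coord("O") is not None):
                co = prev.coord("C") - prev.coord("O")
                norm = np.linalg.norm(co)
                if norm > 1e-9:
                    hpos = res.coord("N") + co / norm * NH_BOND
                    res.atoms["H"] = AtomRecord(
                        "H", *hpos.tolist(), res.plddt)
            prev = res
    return model


def _flatten(model: StructureModel):
    """Residues in file order plus the index where each chain starts."""
    residues, chain_of = [], []
    for ci, chain in enumerate(model.chains):
        for res in chain.residues:
            residues.append(res)
            chain_of.append(ci)
    return residues, np.asarray(chain_of, dtype=int)


def _segments(residues, chain_of) -> np.ndarray:
    """Segment id per residue; increments at chain breaks."""
    n = len(residues)
    seg = np.zeros(n, dtype=int)
    cur = 0
    for i in range(1, n):
        broken = chain_of[i] != chain_of[i - 1]
        if not broken:
            c_prev = residues[i - 1].coord("C")
            n_next = residues[i].coord("N")
            if c_prev is None or n_next is None:
                broken = True
            elif np.linalg.norm(n_next - c_prev) > CHAIN_BREAK_CN:
                broken = True
        if broken:
            cur += 1
        seg[i] = cur
    return seg


def _hbond_matrix(residues, seg) -> np.ndarray:
    """Boolean matrix bond[d, a]: NH of residue d donates to CO of a."""
    n = len(residues)

    def stack(atom):
        out = np.full((n, 3), np.nan)
        for i, r in enumerate(residues):
            xyz = r.coord(atom)
            if xyz is not None:
                out[i] = xyz
        return out

    N, H, C, O = stack("N"), stack("H"), stack("C"), stack("O")

    def dist(a, b):
        # a: donor-side coords (n,3) broadcast vs b acceptor-side (n,3)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return np.maximum(d, MIN_DIST)

    with np.errstate(invalid="ignore", divide="ignore"):
        energy = Q1Q2_F * (1 / dist(N, O) + 1 / dist(H, C)
                           - 1 / dist(H, O) - 1 / dist(N, C))
    bond = energy < HBOND_CUTOFF
    bond &= np.isfinite(energy)
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) <= 1
    same_seg = seg[:, None] == seg[None, :]
    bond[near & same_seg] = False
    np.fill_diagonal(bond, False)
    return bond


def _kappa(residues, seg) -> np.ndarray:
    """CA pseudo-bond bend angle at each residue (degrees; NaN at ends)."""
    n = len(residues)
    kappa = np.full(n, np.nan)
    ca = np.full((n, 3), np.nan)
    for i, r in enumerate(residues):
        xyz = r.coord("CA")
        if xyz is not None:
            ca[i] = xyz
    for i in range(2, n - 2):
        if not (seg[i - 2] == seg[i] == seg[i + 2]):
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9 or not np.isfinite(nu * nv):
            continue
        cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        kappa[i] = np.degrees(np.arccos(cosang))
    return kappa


def assign_ss8(model: StructureModel) -> str:
    """Assign the 8-class DSSP string for all residues of a model.

    Hydrogens are (re)placed internally.  Chains shorter than five
    residues are assigned all '-' with a warning.  Priority on overlap:
    H > E > B > G > I > T > S > '-'.
    """
    place_amide_hydrogens(model)
    residues, chain_of = _flatten(model)
    n = len(residues)
    if n == 0:
        return ""
    seg = _segments(residues, chain_of)
    bond = _hbond_matrix(residues, seg)

    # n-turns: turn_n[i] true when CO(i) accepts from NH(i+n) in-segment
    turns = {}
    for tl in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - tl):
            if seg[i] == seg[i + tl] and bond[i + tl, i]:
                t[i] = True
        turns[tl] = t

    helix = {}          # turn length -> boolean candidate mask
    for tl in (3, 4, 5):
        mask = np.zeros(n, dtype=bool)
        t = turns[tl]
        for i in range(1, n - tl):
            if t[i - 1] and t[i]:
                mask[i:i + tl] = True
        helix[tl] = mask

    # bridges: K&S parallel/antiparallel patterns; Hbond(a<-b) == bond[b, a]
    para = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    interior = np.array(
        [0 < i < n - 1 and seg[i - 1] == seg[i] == seg[i + 1]
         for i in range(n)])
    cand_i, cand_j = np.where(bond | bond.T)
    pairs = set()
    for a, b in zip(cand_i, cand_j):
        for i, j in ((a, b), (b, a), (a - 1, b), (a + 1, b),
                     (a, b - 1), (a, b + 1), (a - 1, b + 1), (a + 1, b - 1)):
            if 0 <= i < n and 0 <= j < n and i < j:
                pairs.add((i, j))
    for i, j in pairs:
        if j - i <= 2 and seg[i] == seg[j]:
            continue
        if not (interior[i] and interior[j]):
            continue
        if (bond[j, i - 1] and bond[i + 1, j]) or \
           (bond[i, j - 1] and bond[j + 1, i]):
            para[i, j] = para[j, i] = True
        if (bond[j, i] and bond[i, j]) or \
           (bond[j + 1, i - 1] and bond[i + 1, j - 1]):
            anti[i, j] = anti[j, i] = True

    bridge = np.zeros(n, dtype=bool)    # isolated bridge -> B
    ladder = np.zeros(n, dtype=bool)    # extended ladder -> E
    bridged = para | anti
    for i, j in pairs:
        if not bridged[i, j]:
            continue
        bridge[i] = bridge[j] = True
        # ladder: a neighbouring bridge of the same type extends this one
        for mat in (para, anti):
            if not mat[i, j]:
                continue
            neighbours = [(i + 1, j + 1), (i - 1, j - 1),
                          (i + 1, j - 1), (i - 1, j + 1)]
            if any(0 <= p < n and 0 <= q < n and mat[p, q]
                   for p, q in neighbours):
                ladder[i] = ladder[j] = True

    # turn T: residues bracketed by an n-turn bond
    turn_t = np.zeros(n, dtype=bool)
    for tl in (3, 4, 5):
        for i in np.flatnonzero(turns[tl]):
            turn_t[i + 1:i + tl] = True

    kappa = _kappa(residues, seg)
    bend = np.nan_to_num(kappa, nan=0.0) > BEND_KAPPA

    ss = np.full(n, "-", dtype="<U1")
    ss[bend] = "S"
    ss[turn_t] = "T"
    ss[helix[5]] = "I"
    ss[helix[3]] = "G"
    ss[bridge] = "B"
    ss[ladder] = "E"
    ss[helix[4]] = "H"
    for i, r in enumerate(residues):
        if r.incomplete:
            ss[i] = "-"

    # short chains carry no assignable structure
    out = "".join(ss)
    pieces, start = [], 0
    for chain in model.chains:
        ln = len(chain.residues)
        piece = out[start:start + ln]
        if ln < 5:
            warnings.warn(
                f"chain {chain.chain_id} has {ln} residues (<5); "
                "assigned all '-'", stacklevel=2)
            piece = "-" * ln
        pieces.append(piece)
        start += ln
    return "".join(pieces)


def reduce_ss(ss8: str) -> str:
    """Reduce an 8-class string to the 4-class H/E/T/C alphabet."""
    try:
        return "".join(_REDUCE[c] for c in ss8)
    except KeyError as exc:
        raise ValueError(f"unknown secondary-structure class {exc}") from exc


def hydrogen_bonds(model: StructureModel) -> list[HydrogenBond]:
    """All recorded H-bonds of a model (donor, acceptor, energy)."""
    place_amide_hydrogens(model)
    residues, chain_of = _flatten(model)
    seg = _segments(residues, chain_of)
    out = []
    for d, res_d in enumerate(residues):
        nd, hd = res_d.coord("N"), res_d.coord("H")
        if nd is None or hd is None:
            continue
        for a, res_a in enumerate(residues):
            if abs(d - a) <= 1 and seg[d] == seg[a]:
                continue
            ca_, oa = res_a.coord("C"), res_a.coord("O")
            if ca_ is None or oa is None:
                continue
            e = hbond_energy(nd, hd, ca_, oa)
            if e < HBOND_CUTOFF:
                out.append(HydrogenBond(d, a, e))
    return out


def read_dssp_file(path) -> str:
    """Extract the 8-class string from a classic ``.dssp`` table file.

    Lets users substitute a reference DSSP implementation for the
    built-in assignment.  Chain-break rows ('!') are skipped; the 'P'
    (PPII) class of newer builds maps to '-'.
    """
    ss = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":
                continue
            c = line[16].upper()
            if c == " " or c == "P":
                c = "-"
            if c not in SS8_ALPHABET:
                c = "-"
            ss.append(c)
    return "".join(ss)
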