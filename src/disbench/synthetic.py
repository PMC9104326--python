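"""Synthetic cohorts for end-to-end testing of the disorder benchmark.

Emulates every input of a structure-based disorder benchmark with stated
statistical structure so that every pipeline stage runs without
downloads:

* two-state (ordered/disordered) Markov segment labels,
* per-residue confidence profiles drawn from two truncated normals with
  controllable separation, smoothed along the chain,
* secondary-structure strings consistent with the labels — with two
  knobs, ``transient_helix_rate`` (disordered segments that fold into
  low-confidence helices) and ``confident_coil_rate`` (ordered residues
  assigned coil at high confidence), which reproduce the mechanism that
  separates the naive secondary-structure rule from confidence-based
  prediction,
* ideal backbone coordinates (helix phi=-57 psi=-47, strand phi=-139
  psi=135, coil from broad allowed regions) for geometry tests,
* structural-coverage intervals biased toward ordered regions,
* emulated external predictor files whose theoretical AUC is set by a
  binormal model.

The generator is fully deterministic given its config (including seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.special import ndtr, ndtri

from .dssp import reduce_ss
from .io_formats import (AtomRecord, Chain, IntervalAnnotation,
                         PredictionFile, ResidueRecord, StructureModel,
                         mask_to_intervals, write_caid_predictions,
                         write_intervals, write_structure)

# ideal backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
PHI_HELIX, PSI_HELIX = -57.0, -47.0
PHI_STRAND, PSI_STRAND = -139.0, 135.0
OMEGA = 180.0
MIN_CA_CA = 2.0         # steric-collapse criterion for coil retries


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; the defaults are the benchmark
    conditions and are not meant to be tuned per run.

    Lengths and cohort size are desk-scale stand-ins for a DisProt-style
    benchmark set; confidence means/sds give well-separated but
    overlapping ordered/disordered states (d' = 4 at the defaults).
    """

    n_proteins: int = 150
    length_range: tuple[int, int] = (60, 400)
    disorder_fraction: float = 0.3
    mean_segment_length: float = 30.0      # mean disordered-segment length
    plddt_ordered: tuple[float, float] = (85.0, 10.0)
    plddt_disordered: tuple[float, float] = (45.0, 10.0)
    smoothing_window: int = 5
    coverage_fraction_ordered: float = 0.9
    coverage_fraction_disordered: float = 0.2
    transient_helix_rate: float = 0.2
    confident_coil_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for frac in (self.disorder_fraction, self.coverage_fraction_ordered,
                     self.coverage_fraction_disordered,
                     self.transient_helix_rate, self.confident_coil_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for mean, _sd in (self.plddt_ordered, self.plddt_disordered):
            if not 0.0 <= mean <= 100.0:
                raise ValueError(f"pLDDT mean {mean} outside [0, 100]")
        if self.mean_segment_length < 2:
            raise ValueError("mean_segment_length must be >= 2")

    @property
    def implied_threshold(self) -> float:
        """Midpoint of the two confidence states (equal-sd crossing)."""
        return 0.5 * (self.plddt_ordered[0] + self.plddt_disordered[0])

    @property
    def d_prime(self) -> float:
        """Separation (mu_o - mu_d) / sigma of the unsmoothed process."""
        sigma = 0.5 * (self.plddt_ordered[1] + self.plddt_disordered[1])
        return (self.plddt_ordered[0] - self.plddt_disordered[0]) / sigma


@dataclass
class Cohort:
    """Everything generated for one synthetic benchmark cohort."""

    config: GeneratorConfig
    accessions: list[str]
    labels: list[np.ndarray]                 # 0 ordered / 1 disordered
    plddt: list[np.ndarray]
    ss8: list[str]
    reduced: list[str]
    disorder_intervals: dict[str, list[tuple[int, int]]]
    coverage_intervals: dict[str, list[tuple[int, int]]]
    predictor_files: dict[str, list[PredictionFile]] = field(
        default_factory=dict)

    def __len__(self) -> int:
        return len(self.accessions)

    @property
    def n_residues(self) -> int:
        return int(sum(len(l) for l in self.labels))


# ---------------------------------------------------------------------------
# label / profile / string generation


def generate_labels(config: GeneratorConfig,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Two-state Markov segment labels per protein.

    Disordered segments have mean length ``mean_segment_length``; the
    ordered-state exit rate is set so the stationary disorder fraction
    equals ``disorder_fraction``.
    """
    d = config.disorder_fraction
    if d <= 0.0:
        return [np.zeros(n, dtype=np.int8) for n in _lengths(config, rng)]
    if d >= 1.0:
        return [np.ones(n, dtype=np.int8) for n in _lengths(config, rng)]
    q_d = 1.0 / config.mean_segment_length          # disordered -> ordered
    mean_ordered = config.mean_segment_length * (1.0 - d) / d
    q_o = 1.0 / max(mean_ordered, 1.0)              # ordered -> disordered
    out = []
    for n in _lengths(config, rng):
        labels = np.empty(n, dtype=np.int8)
        state = int(rng.random() < d)
        for i in range(n):
            labels[i] = state
            q = q_d if state == 1 else q_o
            if rng.random() < q:
                state = 1 - state
        out.append(labels)
    return out


def _lengths(config: GeneratorConfig, rng: np.random.Generator):
    lo, hi = config.length_range
    return rng.integers(lo, hi + 1, size=config.n_proteins)


def generate_plddt(labels: list[np.ndarray], config: GeneratorConfig,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Confidence profiles: state-conditional normals, clipped to [0,100],
    then moving-average smoothed over ``smoothing_window`` residues."""
    mu_o, sd_o = config.plddt_ordered
    mu_d, sd_d = config.plddt_disordered
    out = []
    for lab in labels:
        mu = np.where(lab == 1, mu_d, mu_o)
        sd = np.where(lab == 1, sd_d, sd_o)
        raw = np.clip(rng.normal(mu, sd), 0.0, 100.0)
        if config.smoothing_window > 1:
            raw = uniform_filter1d(raw, size=config.smoothing_window,
                                   mode="nearest")
        out.append(raw)
    return out


def generate_ss(labels: list[np.ndarray], config: GeneratorConfig,
                rng: np.random.Generator) -> list[tuple[str, str]]:
    """8-class + reduced secondary-structure strings consistent with labels.

    Ordered segments carry helix/strand runs joined by turn linkers;
    disordered segments are loop/bend — except that a
    ``transient_helix_rate`` fraction of disordered segments fold into
    helices (DSSPp will wrongly call them ordered) and a
    ``confident_coil_rate`` fraction of ordered runs are written as coil
    (DSSPp will wrongly call them disordered).
    """
    out = []
    for lab in labels:
        chars = np.empty(len(lab), dtype="<U1")
        for start, end in _runs(lab):
            seg_len = end - start
            if lab[start] == 1:                      # disordered segment
                if rng.random() < config.transient_helix_rate:
                    chars[start:end] = "H"
                else:
                    bend = rng.random(seg_len) < 0.2
                    chars[start:end] = np.where(bend, "S", "-")
            else:                                    # ordered segment
                pos = start
                while pos < end:
                    run = int(min(end - pos, rng.integers(5, 13)))
                    kind = "H" if rng.random() < 0.6 else "E"
                    if rng.random() < config.confident_coil_rate:
                        kind = "-"
                    chars[pos:pos + run] = kind
                    pos += run
                    link = int(min(end - pos, 2))
                    if link and pos < end:
                        chars[pos:pos + link] = "T"
                        pos += link
        ss8 = "".join(chars)
        out.append((ss8, reduce_ss(ss8)))
    return out


def _runs(labels: np.ndarray):
    """(start, end) half-open runs of constant value."""
    edges = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], edges, [len(labels)]))
    return list(zip(bounds[:-1], bounds[1:]))


def generate_coverage(labels: list[np.ndarray], config: GeneratorConfig,
                      rng: np.random.Generator
                      ) -> list[list[tuple[int, int]]]:
    """Per-residue Bernoulli coverage, biased toward ordered residues,
    merged into 1-based inclusive intervals."""
    out = []
    for lab in labels:
        p = np.where(lab == 1, config.coverage_fraction_disordered,
                     config.coverage_fraction_ordered)
        covered = rng.random(len(lab)) < p
        out.append(mask_to_intervals(covered))
    return out


def expected_masked_fraction(config: GeneratorConfig) -> float:
    """Closed-form DisProt-PDB masked fraction under the generator.

    Disorder intervals are exact label runs, so disordered residues are
    always annotated; only ordered, uncovered residues are masked.
    """
    return ((1.0 - config.disorder_fraction)
            * (1.0 - config.coverage_fraction_ordered))


def binormal_auc(d_prime: float) -> float:
    """Theoretical AUC of the equal-variance binormal score model."""
    return float(ndtr(d_prime / math.sqrt(2.0)))


def generate_predictor_files(labels: list[np.ndarray], accuracy_auc: float,
                             rng: np.random.Generator,
                             accessions: list[str] | None = None,
                             name: str = "emulated"
                             ) -> list[PredictionFile]:
    """Emulated external predictor output at a target theoretical AUC.

    Scores come from the equal-variance binormal model (disordered
    residues shifted by sqrt(2) * Phi^-1(AUC)) pushed through the normal
    CDF so they live in [0, 1]; binary labels cut at the equal-error
    threshold.  ``accuracy_auc == 1`` degenerates to a perfect predictor.
    """
    if not 0.5 <= accuracy_auc <= 1.0:
        raise ValueError("accuracy_auc outside [0.5, 1]")
    if accessions is None:
        accessions = [f"SYN{i:04d}" for i in range(len(labels))]
    out = []
    for acc, lab in zip(accessions, labels):
        n = len(lab)
        if accuracy_auc >= 1.0:
            scores = lab.astype(float)
            calls = lab.astype(int)
        else:
            mu1 = math.sqrt(2.0) * ndtri(accuracy_auc)
            z = rng.normal(lab * mu1, 1.0)
            scores = ndtr(z - mu1 / 2.0)
            calls = (scores >= 0.5).astype(int)
        out.append(PredictionFile(
            accession=acc, positions=np.arange(1, n + 1),
            residues=["A"] * n, scores=scores, labels=calls))
    return out


# ---------------------------------------------------------------------------
# backbone geometry


def _place_atom(a, b, c, bond: float, angle: float,
                torsion: float) -> np.ndarray:
    """NeRF placement of atom d given a-b-c, internal coordinates in
    Angstrom/degrees (torsion about the b-c axis)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsions_for(ss_char: str, rng: np.random.Generator):
    if ss_char in "Hh":
        return PHI_HELIX, PSI_HELIX
    if ss_char in "Ee":
        return PHI_STRAND, PSI_STRAND
    # coil: broad allowed basins (beta/PPII or alpha-left flank)
    if rng.random() < 0.7:
        return (float(rng.uniform(-160.0, -60.0)),
                float(rng.uniform(90.0, 175.0)))
    return (float(rng.uniform(-160.0, -60.0)),
            float(rng.uniform(-70.0, -10.0)))


def generate_backbone(ss_spec: str, seed: int = 0, chain_id: str = "A",
                      plddt: float | np.ndarray = 90.0,
                      max_retries: int = 100) -> StructureModel:
    """Build ideal backbone coordinates for a secondary-structure spec.

    ``ss_spec`` is one character per residue over {H, E, C}.  Coil
    torsions are resampled (up to ``max_retries`` times) whenever any
    non-adjacent CA pair comes within 2 A.
    """
    if not set(ss_spec) <= set("HEC"):
        raise ValueError("ss_spec must be over {H, E, C}")
    rng = np.random.default_rng(seed)
    n = len(ss_spec)
    plddt_arr = (np.full(n, plddt, dtype=float)
                 if np.isscalar(plddt) else np.asarray(plddt, dtype=float))
    for _attempt in range(max_retries):
        coords = _build_chain(ss_spec, rng)
        ca = coords[:, 1, :]
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        iu = np.triu_indices(n, k=2)
        if "C" not in ss_spec or (d[iu] >= MIN_CA_CA).all():
            break
    return _coords_to_model(coords, plddt_arr, chain_id)


def _build_chain(ss_spec: str, rng: np.random.Generator) -> np.ndarray:
    """(n, 4, 3) array of N, CA, C, O positions by sequential placement."""
    n = len(ss_spec)
    torsions = [_torsions_for(c, rng) for c in ss_spec]
    coords = np.zeros((n, 4, 3))
    # seed residue along x
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [B_N_CA, 0.0, 0.0]
    ang = math.radians(A_N_CA_C)
    coords[0, 2] = coords[0, 1] + B_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n):
        phi_next = torsions[i + 1][0] if i + 1 < n else None
        psi = torsions[i][1]
        if i + 1 < n:
            n_next = _place_atom(coords[i, 0], coords[i, 1], coords[i, 2],
                                 B_C_N, A_CA_C_N, psi)
            coords[i + 1, 0] = n_next
            coords[i + 1, 1] = _place_atom(coords[i, 1], coords[i, 2],
                                           n_next, B_N_CA, A_C_N_CA, OMEGA)
            coords[i + 1, 2] = _place_atom(coords[i, 2], n_next,
                                           coords[i + 1, 1], B_CA_C,
                                           A_N_CA_C, phi_next)
        # carbonyl O: anti-periplanar to the next N (torsion psi + 180)
        coords[i, 3] = _place_atom(coords[i, 0], coords[i, 1], coords[i, 2],
                                   B_C_O, A_CA_C_O, psi + 180.0)
    return coords


def _coords_to_model(coords: np.ndarray, plddt: np.ndarray,
                     chain_id: str, start_index: int = 1) -> StructureModel:
    chain = Chain(chain_id=chain_id)
    for i in range(coords.shape[0]):
        atoms = {}
        for j, name in enumerate(("N", "CA", "C", "O")):
            x, y, z = coords[i, j]
            atoms[name] = AtomRecord(name, float(x), float(y), float(z),
                                     float(plddt[i]))
        chain.residues.append(ResidueRecord(
            index=start_index + i, name="ALA", chain_id=chain_id,
            atoms=atoms, plddt=float(plddt[i])))
    return StructureModel(chains=[chain], name="synthetic")


_PAIR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def generate_strand_pair(n_residues: int = 6, seed: int = 0,
                         plddt: float = 90.0) -> StructureModel:
    """Two antiparallel ideal strands placed at hydrogen-bond register.

    The second strand is flipped 180 degrees and translated; the offset
    is chosen by a deterministic grid search maximising the number of
    inter-chain Kabsch-Sander hydrogen bonds.  Ideal strand geometry is
    seed-independent, so the placement is cached per strand length.
    """
    if n_residues not in _PAIR_CACHE:
        _PAIR_CACHE[n_residues] = _place_strand_pair(n_residues)
    coords_a, coords_b = _PAIR_CACHE[n_residues]
    model = _coords_to_model(coords_a, np.full(n_residues, plddt), "A")
    model_b = _coords_to_model(coords_b, np.full(n_residues, plddt), "B")
    model.chains.append(model_b.chains[0])
    model.name = "strand_pair"
    return model


def _amide_h(coords: np.ndarray) -> np.ndarray:
    """Ideal amide H per residue (NaN at the chain start)."""
    h = np.full((coords.shape[0], 3), np.nan)
    for i in range(1, coords.shape[0]):
        co = coords[i - 1, 2] - coords[i - 1, 3]
        h[i] = coords[i, 0] + co / np.linalg.norm(co)
    return h


def _place_strand_pair(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    from .dssp import HBOND_CUTOFF, MIN_DIST, Q1Q2_F

    coords_a = _build_chain("E" * n_residues, np.random.default_rng(0))
    # align the strand axis (first->last CA) with x, centre at the origin
    axis = coords_a[-1, 1] - coords_a[0, 1]
    rot = _rotation_onto(axis, np.array([1.0, 0.0, 0.0]))
    coords_a = coords_a @ rot.T
    coords_a -= coords_a[:, 1, :].mean(axis=0)
    h_a = _amide_h(coords_a)

    offsets = np.array([[dx, dy, dz]
                        for dy in np.arange(4.0, 5.8, 0.15)
                        for dx in np.arange(-3.5, 3.5, 0.25)
                        for dz in np.arange(-2.0, 2.0, 0.25)])

    def pair_score(don_n, don_h, acc_c, acc_o, t_sign):
        """Soft bond count for all offsets; B-side atoms get +-t."""
        valid = np.isfinite(don_h).all(axis=1)

        def dists(p, q):      # (i,3) donor vs (j,3) acceptor -> (m,i,j)
            base = q[None, :, :] - p[:, None, :]
            d = np.linalg.norm(base[None] + t_sign *
                               offsets[:, None, None, :], axis=-1)
            return np.maximum(d, MIN_DIST)

        e = Q1Q2_F * (1 / dists(don_n, acc_o) + 1 / dists(don_h, acc_c)
                      - 1 / dists(don_h, acc_o) - 1 / dists(don_n, acc_c))
        e = np.where(valid[None, :, None], e, 0.0)
        bonded = e < HBOND_CUTOFF
        soft = np.where(bonded,
                        1.0 - 0.01 * np.maximum(e + 4.0, 0.0), 0.0)
        return soft.sum(axis=(1, 2))

    best = None
    for flip_axis in (0, 1, 2):
        mirror = -np.ones(3)
        mirror[flip_axis] = 1.0
        cb = coords_a * mirror
        h_b = h_a * mirror
        # A donates to B (+t on acceptor) and B donates to A (-t on A rel.)
        score = (pair_score(coords_a[:, 0], h_a, cb[:, 2], cb[:, 3], +1)
                 + pair_score(cb[:, 0], h_b, coords_a[:, 2],
                              coords_a[:, 3], -1))
        k = int(np.argmax(score))
        if best is None or score[k] > best[0]:
            best = (float(score[k]), cb + offsets[k])
    return coords_a, best[1]


def _model_coords(model: StructureModel) -> np.ndarray:
    res = model.residues
    out = np.zeros((len(res), 4, 3))
    for i, r in enumerate(res):
        for j, name in enumerate(("N", "CA", "C", "O")):
            out[i, j] = r.coord(name)
    return out


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending direction a onto direction b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# cohort assembly and serialisation


def generate_cohort(config: GeneratorConfig,
                    predictor_aucs: dict[str, float] | None = None
                    ) -> Cohort:
    """Generate a full synthetic benchmark cohort from one config."""
    rng = np.random.default_rng(config.seed)
    labels = generate_labels(config, rng)
    plddt = generate_plddt(labels, config, rng)
    ss = generate_ss(labels, config, rng)
    coverage = generate_coverage(labels, config, rng)
    accessions = [f"SYN{i:04d}" for i in range(len(labels))]
    disorder = {acc: mask_to_intervals(lab == 1)
                for acc, lab in zip(accessions, labels)}
    cohort = Cohort(
        config=config, accessions=accessions, labels=labels, plddt=plddt,
        ss8=[s[0] for s in ss], reduced=[s[1] for s in ss],
        disorder_intervals=disorder,
        coverage_intervals=dict(zip(accessions, coverage)))
    if predictor_aucs:
        for name, auc in predictor_aucs.items():
            cohort.predictor_files[name] = generate_predictor_files(
                labels, auc, rng, accessions=accessions, name=name)
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path,
                 write_structures: bool = False,
                 max_structures: int = 10) -> None:
    """Serialise a cohort: interval TSVs, CAID files, manifest JSON, and
    (optionally) PDB files with pLDDT in the B-factor column."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_intervals(
        [IntervalAnnotation(a, iv, "disorder")
         for a, iv in cohort.disorder_intervals.items() if iv],
        outdir / "disorder.tsv")
    write_intervals(
        [IntervalAnnotation(a, iv, "pdb_coverage")
         for a, iv in cohort.coverage_intervals.items() if iv],
        outdir / "coverage.tsv")
    for name, files in cohort.predictor_files.items():
        write_caid_predictions(files, outdir / f"pred_{name}.caid")
    plddt_files = [PredictionFile(
        accession=a, positions=np.arange(1, len(p) + 1),
        residues=["A"] * len(p), scores=np.round(1 - p / 100.0, 6))
        for a, p in zip(cohort.accessions, cohort.plddt)]
    write_caid_predictions(plddt_files, outdir / "tpld.caid")
    with open(outdir / "ss.tsv", "w") as fh:
        fh.write("accession\tss8\treduced\n")
        for a, s8, red in zip(cohort.accessions, cohort.ss8, cohort.reduced):
            fh.write(f"{a}\t{s8}\t{red}\n")
    if write_structures:
        sdir = outdir / "structures"
        sdir.mkdir(exist_ok=True)
        for a, red, p in list(zip(cohort.accessions, cohort.reduced,
                                  cohort.plddt))[:max_structures]:
            spec = "".join("H" if c == "H" else "E" if c == "E" else "C"
                           for c in red)
            model = generate_backbone(spec, seed=cohort.config.seed,
                                      plddt=p)
            write_structure(model, sdir / f"{a}.pdb")
    manifest = {"config": asdict(cohort.config),
                "n_proteins": len(cohort),
                "n_residues": cohort.n_residues,
                "predictors": sorted(cohort.predictor_files)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
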