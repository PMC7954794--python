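"""Seeded generators emulating every input the scoring stages consume.

Each generator mirrors the statistical structure of one experimental data
type: colony-size plate grids with a control border, plate offsets and
planted interactions; growth-assay plates with injected inter-plate
discordance; protein sequence sets with motifs planted from given PWMs;
saturation-mutagenesis count tables with known per-variant fitness effects;
interaction-profile matrices with tunable coupling to sequence divergence;
and inward-drifting particle tracks with stochastic disassembly.

All generators draw from an explicit integer seed through a local
numpy Generator; no global RNG state. Identical configuration implies
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dms import CODONS, CODON_TO_AA, DMSCountTable
from .motif import PWM, YEAST_AA_FREQS, AA_INDEX
from .plates import PlateGrid
from .seqstruct import AA_ALPHABET
from .tracks import Track

BORDER_CONTROL = "BORDER_CONTROL"  # control bait-prey pair filling the frame


@dataclass(frozen=True)
class SimConfig:
    """Shared knobs for the plate-grid generators (log2 colony-size space)."""

    seed: int = 0
    n_rows: int = 32
    n_cols: int = 48
    border_width: int = 2
    background_log2: float = 10.0
    plate_sd: float = 0.25
    noise_sd: float = 0.25
    effect_log2: float = 4.0
    frac_positive: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.frac_positive <= 1:
            raise ValueError("frac_positive must be in [0, 1]")
        if self.border_width < 0:
            raise ValueError("border_width must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    planted_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    dms_effects: dict[tuple[int, str], float] = field(default_factory=dict)
    motif_positions: dict[str, int | None] = field(default_factory=dict)
    coupling: float | None = None
    track_params: dict = field(default_factory=dict)
    track_complete: dict[str, bool] = field(default_factory=dict)
    track_end_frame: dict[str, int] = field(default_factory=dict)
    track_tail_start: dict[str, int | None] = field(default_factory=dict)


def _inner_positions(cfg: SimConfig) -> list[tuple[int, int]]:
    b = cfg.border_width
    return [
        (r, c)
        for r in range(b, cfg.n_rows - b)
        for c in range(b, cfg.n_cols - b)
    ]


def _border_positions(cfg: SimConfig) -> list[tuple[int, int]]:
    inner = set(_inner_positions(cfg))
    return [
        (r, c)
        for r in range(cfg.n_rows)
        for c in range(cfg.n_cols)
        if (r, c) not in inner
    ]


def _place_preys(
    preys: Sequence[str],
    positions: list[tuple[int, int]],
    copies: int,
    rng: np.random.Generator,
) -> dict[tuple[int, int], str]:
    """Randomized prey placement; a prey's copies are never grid-adjacent."""
    need = len(preys) * copies
    if need > len(positions):
        raise ValueError(
            f"grid too small: {need} prey positions needed, {len(positions)} available"
        )
    idx = rng.permutation(len(positions))[:need]
    slots = [positions[i] for i in idx]
    assign = {}
    for i, prey in enumerate(preys):
        assign[prey] = slots[i * copies:(i + 1) * copies]
    # fix-up: swap away adjacent duplicate pairs
    def adjacent(a, b):
        return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1

    prey_list = list(preys)
    for _ in range(100):
        bad = [p for p in prey_list
               if any(adjacent(a, b)
                      for i, a in enumerate(assign[p])
                      for b in assign[p][i + 1:])]
        if not bad:
            break
        for p in bad:
            other = prey_list[int(rng.integers(len(prey_list)))]
            if other == p:
                continue
            i = int(rng.integers(len(assign[p])))
            j = int(rng.integers(len(assign[other])))
            assign[p][i], assign[other][j] = assign[other][j], assign[p][i]
    out = {}
    for prey, pos_list in assign.items():
        for pos in pos_list:
            out[pos] = prey
    return out


def gen_plate_screen(
    cfg: SimConfig,
    baits: Sequence[str],
    preys: Sequence[str],
    effects: Mapping[tuple[str, str], float] | None = None,
    n_plates: int = 2,
    positions_per_prey: int = 2,
) -> tuple[list[PlateGrid], GroundTruth]:
    """Simulate a colony-array interaction screen.

    Each bait is screened on `n_plates` plates with each prey at
    `positions_per_prey` randomized positions per plate (defaults give the
    four independent bait-prey tests of the screen design). Colony log2
    sizes are background + per-plate offset + planted effect + Gaussian
    noise. When `effects` is omitted, a fraction `cfg.frac_positive` of
    preys per bait is planted at `cfg.effect_log2`.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    if effects is None:
        effects = {}
        for bait in baits:
            n_pos = int(round(cfg.frac_positive * len(preys)))
            chosen = rng.choice(len(preys), size=n_pos, replace=False)
            for j in chosen:
                effects[(bait, preys[j])] = cfg.effect_log2
    truth.planted_pairs = dict(effects)

    inner = _inner_positions(cfg)
    border = _border_positions(cfg)
    grids: list[PlateGrid] = []
    for bait in baits:
        for k in range(n_plates):
            offset = rng.normal(0.0, cfg.plate_sd)
            placement = _place_preys(preys, inner, positions_per_prey, rng)
            rows = []
            for (r, c) in border:
                val = cfg.background_log2 + offset + rng.normal(0.0, cfg.noise_sd)
                rows.append({"row": r, "col": c, "prey": BORDER_CONTROL,
                             "is_border": True, "log2_size": val, "qc_pass": True})
            for (r, c) in inner:
                prey = placement.get((r, c))
                if prey is None:
                    continue
                eff = effects.get((bait, prey), 0.0)
                val = (cfg.background_log2 + offset + eff
                       + rng.normal(0.0, cfg.noise_sd))
                rows.append({"row": r, "col": c, "prey": prey,
                             "is_border": False, "log2_size": val, "qc_pass": True})
            df = pd.DataFrame(rows).sort_values(["row", "col"]).reset_index(drop=True)
            grids.append(PlateGrid(plate_id=f"{bait}_p{k + 1}", bait=bait, df=df))
    return grids, truth


def gen_growth_plates(
    cfg: SimConfig,
    strains: Sequence[str],
    discordant: set[str] | frozenset[str] = frozenset(),
    conditions: Sequence[str] = ("condition_1",),
    replicates_per_plate: int = 6,
    strain_effects: Mapping[str, float] | None = None,
    discordant_shift: float = 3.0,
    timepoint_h: float = 74.0,
) -> list[PlateGrid]:
    """Simulate stress-condition growth plates: two plate replicates per
    condition, each strain at `replicates_per_plate` random positions per
    plate (12 replicates per strain with the defaults). Strains listed in
    `discordant` receive a `discordant_shift` log2 offset on the second
    plate only, exceeding the downstream discordance cutoff."""
    rng = np.random.default_rng(cfg.seed)
    inner = _inner_positions(cfg)
    border = _border_positions(cfg)
    effects = dict(strain_effects or {})
    plates: list[PlateGrid] = []
    for condition in conditions:
        for k in range(2):
            offset = rng.normal(0.0, cfg.plate_sd)
            placement = _place_preys(strains, inner, replicates_per_plate, rng)
            rows = []
            for (r, c) in border:
                val = cfg.background_log2 + offset + rng.normal(0.0, cfg.noise_sd)
                rows.append({"row": r, "col": c, "prey": BORDER_CONTROL,
                             "is_border": True, "log2_size": val, "qc_pass": True})
            for (r, c), strain in sorted(placement.items()):
                val = (cfg.background_log2 + offset + effects.get(strain, 0.0)
                       + rng.normal(0.0, cfg.noise_sd))
                if k == 1 and strain in discordant:
                    val += discordant_shift
                rows.append({"row": r, "col": c, "prey": strain,
                             "is_border": False, "log2_size": val, "qc_pass": True})
            df = pd.DataFrame(rows).sort_values(["row", "col"]).reset_index(drop=True)
            plates.append(PlateGrid(plate_id=f"{condition}_p{k + 1}", bait="",
                                    df=df, condition=condition,
                                    timepoint_h=timepoint_h))
    return plates


def _sample_from_pwm(pwm: PWM, rng: np.random.Generator) -> str:
    out = []
    for i in range(pwm.width):
        j = rng.choice(len(AA_ALPHABET), p=pwm.f[i] / pwm.f[i].sum())
        out.append(AA_ALPHABET[j])
    return "".join(out)


def gen_motif_dataset(
    pwms: Sequence[PWM],
    n_dep: int,
    n_indep: int,
    length: int = 100,
    planted_frac: float = 1.0,
    background: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Sequence sets for motif-enrichment testing.

    "Dependent" sequences carry, with probability `planted_frac`, a window
    sampled column-wise from one of the PWMs (assigned round-robin) at a
    recorded position; all remaining residues, and all "independent"
    sequences, are drawn from the background amino-acid composition.
    Returns (dependent id->seq, independent id->seq, ground truth).
    """
    if not 0 <= planted_frac <= 1:
        raise ValueError("planted_frac must be in [0, 1]")
    if length < max(p.width for p in pwms):
        raise ValueError("sequences must be at least as long as the widest PWM")
    rng = np.random.default_rng(seed)
    letters = np.array(list((background or YEAST_AA_FREQS).keys()))
    probs = np.array(list((background or YEAST_AA_FREQS).values()), dtype=float)
    probs = probs / probs.sum()
    truth = GroundTruth()

    def background_seq() -> str:
        return "".join(rng.choice(letters, size=length, p=probs))

    dependent = {}
    for i in range(n_dep):
        sid = f"dep_{i:04d}"
        seq = background_seq()
        pwm = pwms[i % len(pwms)]
        if rng.random() < planted_frac:
            start = int(rng.integers(0, length - pwm.width + 1))
            motif = _sample_from_pwm(pwm, rng)
            seq = seq[:start] + motif + seq[start + pwm.width:]
            truth.motif_positions[sid] = start
        else:
            truth.motif_positions[sid] = None
        dependent[sid] = seq
    independent = {f"ind_{i:04d}": background_seq() for i in range(n_indep)}
    return dependent, independent, truth


def gen_dms_counts(
    wt_codons: Sequence[str],
    depth: int = 5000,
    effects: Mapping[tuple[int, str], float] | None = None,
    n_reps: int = 2,
    seed: int = 0,
) -> tuple[list[DMSCountTable], GroundTruth]:
    """Saturation-mutagenesis count tables with known fitness effects.

    One library per codon position (all 64 codons, NNN design). Reference
    counts are multinomial over the variants at each position; selection
    counts are multinomial with weights proportional to the realized
    reference frequency times 2^effect. Effects are keyed by (1-based
    position, codon); variants without an entry (including synonymous
    substitutions) have effect 0.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    effects = dict(effects or {})
    n_pos = len(wt_codons)
    for (pos, codon) in effects:
        if codon not in CODON_TO_AA:
            raise KeyError(f"unknown codon {codon!r} in effects")
        if not 1 <= pos <= n_pos:
            raise KeyError(f"effect position {pos} outside 1..{n_pos}")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(dms_effects=dict(effects))
    wt_map = {i + 1: wt_codons[i].upper() for i in range(n_pos)}
    tables: list[DMSCountTable] = []
    for rep in range(1, n_reps + 1):
        ref_counts: dict[tuple[int, str], int] = {}
        sel_counts: dict[tuple[int, str], int] = {}
        for pos in range(1, n_pos + 1):
            p_ref = np.full(len(CODONS), 1.0 / len(CODONS))
            ref = rng.multinomial(depth, p_ref)
            w = ref.astype(float) * np.array(
                [2.0 ** effects.get((pos, c), 0.0) for c in CODONS]
            )
            if w.sum() <= 0:
                raise ValueError(f"position {pos}: all selection weights zero")
            sel = rng.multinomial(depth, w / w.sum())
            for c, rc, sc in zip(CODONS, ref, sel):
                ref_counts[(pos, c)] = int(rc)
                sel_counts[(pos, c)] = int(sc)
        depths = {pos: depth for pos in range(1, n_pos + 1)}
        tables.append(DMSCountTable(condition="reference", replicate=rep,
                                    counts=ref_counts, depth=dict(depths),
                                    wt_codons=dict(wt_map)))
        tables.append(DMSCountTable(condition="selection", replicate=rep,
                                    counts=sel_counts, depth=dict(depths),
                                    wt_codons=dict(wt_map)))
    return tables, truth


def _random_tree_sequences(
    n_leaves: int, length: int, rng: np.random.Generator
) -> dict[str, str]:
    """Sequences evolved along a random bifurcating tree.

    Each internal split adds an independent divergence step: every site
    mutates with probability 1 - exp(-branch_length) to a random different
    residue. Equal lengths, no indels, so the set is trivially aligned.
    """
    root = "".join(rng.choice(list(AA_ALPHABET), size=length))

    def mutate(seq: str, bl: float) -> str:
        p = 1.0 - np.exp(-bl)
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < p:
                choices = [a for a in AA_ALPHABET if a != chars[i]]
                chars[i] = choices[int(rng.integers(19))]
        return "".join(chars)

    # iterative random bifurcation: start from the root lineage and split a
    # random lineage until n_leaves lineages exist, each split adding an
    # exponential branch of divergence to both children
    lineages = [root]
    while len(lineages) < n_leaves:
        i = int(rng.integers(len(lineages)))
        parent = lineages.pop(i)
        bl1, bl2 = rng.exponential(0.3, size=2)
        lineages.append(mutate(parent, bl1))
        lineages.append(mutate(parent, bl2))
    return {f"dom_{i:03d}": s for i, s in enumerate(lineages)}


def gen_coupled_profiles(
    n_domains: int,
    n_preys: int,
    coupling: float,
    seed: int = 0,
    seq_length: int = 60,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Interaction profiles with tunable coupling to sequence divergence.

    Sequences evolve along a random tree; the sequence distance matrix is
    clustered and its cophenetic (ultrametric) distances are embedded
    exactly into Euclidean coordinates by classical multidimensional
    scaling. Profile rows mix that embedding with independent Gaussian
    noise: profiles = coupling * embedding + (1 - coupling) * noise, so the
    expected cophenetic correlation between the profile dendrogram and the
    sequence dendrogram increases monotonically with `coupling`; at
    coupling 1 it equals 1 exactly (when n_preys >= n_domains - 1), and at
    coupling 0 profiles are independent of the sequences.
    """
    if n_domains < 3:
        raise ValueError("need at least three domains")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    from .trees import cluster, sequence_distance
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(seed)
    aligned = _random_tree_sequences(n_domains, seq_length, rng)
    ids = list(aligned)
    seq_tree = cluster(sequence_distance(aligned))
    C = squareform(hierarchy.cophenet(seq_tree.linkage_matrix))
    order = [seq_tree.labels.index(i) for i in ids]
    C = C[np.ix_(order, order)]

    # classical MDS: exact Euclidean embedding of the ultrametric
    n = n_domains
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (C ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    keep = vals > 1e-10 * max(vals.max(), 1.0)
    E = vecs[:, keep] * np.sqrt(vals[keep])
    dim = min(E.shape[1], n_preys)
    coords = np.zeros((n, n_preys))
    coords[:, :dim] = E[:, :dim]

    scale = float(np.std(E)) if E.size else 1.0
    noise = rng.normal(0.0, scale if scale > 0 else 1.0, size=(n, n_preys))
    profiles = coupling * coords + (1.0 - coupling) * noise
    cols = [f"prey_{j:03d}" for j in range(n_preys)]
    return pd.DataFrame(profiles, index=ids, columns=cols), aligned


def gen_tracks(
    n_tracks: int,
    frame_rate: float = 1.0,
    duration_s: float = 180.0,
    drift: float = 0.3,
    noise_sd: float = 0.1,
    disassembly_rate: float = 0.02,
    seed: int = 0,
    cell_radius: float = 20.0,
    outward_tail_frac: float = 0.0,
    tail_frames: int = 8,
    tail_step: float = 2.5,
) -> tuple[list[Track], GroundTruth]:
    """Inward-drifting particle tracks with geometric disassembly.

    Each track starts near the cell boundary and moves toward the centroid
    at `drift` px/frame with isotropic Gaussian noise; a geometric per-frame
    disassembly hazard ends it. Tracks alive at acquisition end are flagged
    incomplete in the ground truth. With `outward_tail_frac` > 0, a fraction
    of completed tracks get a spurious outward tail appended (and its start
    recorded) to exercise trajectory trimming; the tail moves away from the
    centroid at `tail_step` px/frame, emulating the abrupt jumps that
    mis-linked detections produce.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_frames_total = int(round(frame_rate * duration_s))
    truth = GroundTruth(track_params={
        "drift": drift, "noise_sd": noise_sd,
        "disassembly_rate": disassembly_rate,
        "n_frames_total": n_frames_total,
    })
    tracks: list[Track] = []
    centroid = np.zeros(2)
    for i in range(n_tracks):
        tid = f"track_{i:04d}"
        if disassembly_rate > 0:
            lifetime = int(rng.geometric(disassembly_rate))
        else:
            lifetime = n_frames_total + 1
        n_frames = min(lifetime, n_frames_total)
        complete = lifetime < n_frames_total
        theta = rng.uniform(0, 2 * np.pi)
        pos = 0.9 * cell_radius * np.array([np.cos(theta), np.sin(theta)])
        xy = [pos.copy()]
        for _ in range(n_frames - 1):
            to_center = centroid - pos
            dist = np.linalg.norm(to_center)
            step = (drift * to_center / dist) if dist > drift else to_center
            pos = pos + step + rng.normal(0.0, noise_sd, size=2)
            xy.append(pos.copy())
        tail_start: int | None = None
        if complete and rng.random() < outward_tail_frac:
            tail_start = len(xy)
            away = pos - centroid
            norm = np.linalg.norm(away)
            direction = away / norm if norm > 0 else np.array([1.0, 0.0])
            for _ in range(tail_frames):
                pos = pos + tail_step * direction + rng.normal(0.0, noise_sd, size=2)
                xy.append(pos.copy())
        frames = np.arange(len(xy))
        tracks.append(Track(track_id=tid, cell_id="cell_0",
                            frames=frames, xy=np.array(xy),
                            centroid=centroid.copy()))
        truth.track_complete[tid] = complete
        truth.track_end_frame[tid] = n_frames - 1
        truth.track_tail_start[tid] = tail_start
    return tracks, truth


# The two linker-encoding DNA sequences used when a domain is excised and
# replaced in situ, with their peptide translations, as printed in the
# study design; kept as fixtures for translation checks.
STUFFER_PAIRS: list[tuple[str, str]] = [
    ("GGCGGAAGTTCTGGAGGTGGTGGT", "GGSSGGGG"),
    ("GGTGGCTCAGGAGGAGGTGGTGGA", "GGSGGGGG"),
]


def translate_check_fixtures() -> list[tuple[str, str]]:
    """The two stuffer-linker (DNA, peptide) pairs, for translation tests."""
    return list(STUFFER_PAIRS)
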