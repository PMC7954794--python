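"""MATCH-style matrix similarity scoring of peptide PWMs against proteins.

A PWM here is a k x 20 column-stochastic frequency matrix over the amino-acid
alphabet. Each position i carries an information weight

    I(i) = sum_b f(i, b) * ln(20 * f(i, b))        (0 * ln 0 := 0)

which is zero for a uniform column and ln(20) for a one-hot column. A window
w of length k scores

    MSS(w) = (sum_i I(i) f(i, w_i) - Min) / (Max - Min)

with Min/Max the information-weighted sums of the per-column minimum/maximum
frequencies, so a perfect consensus match scores exactly 1 and the worst
window exactly 0. Scanning takes the maximum over all windows of a sequence
(and over all PWMs assigned to a domain when a domain has several).

Two permutation nulls accompany the scan: random peptides drawn from a
background amino-acid composition, and re-assignment of PWMs to domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .seqstruct import AA_ALPHABET

AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Amino-acid background frequencies of the S. cerevisiae proteome (rounded,
# renormalized); used as the default composition for random peptides.
YEAST_AA_FREQS: dict[str, float] = {
    "A": 0.0547, "C": 0.0127, "D": 0.0579, "E": 0.0649, "F": 0.0450,
    "G": 0.0496, "H": 0.0217, "I": 0.0655, "K": 0.0729, "L": 0.0957,
    "M": 0.0209, "N": 0.0614, "P": 0.0438, "Q": 0.0393, "R": 0.0445,
    "S": 0.0905, "T": 0.0592, "V": 0.0556, "W": 0.0104, "Y": 0.0338,
}


def information_vector(f: np.ndarray) -> np.ndarray:
    """MATCH information weights I(i) = sum_b f(i,b) ln(20 f(i,b))."""
    f = np.asarray(f, dtype=float)
    if (f < 0).any():
        raise ValueError("negative frequencies in PWM")
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("PWM columns must each sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(20.0 * f), 0.0)
    return terms.sum(axis=1)


@dataclass
class PWM:
    """Position weight matrix: k x 20 frequencies plus information weights."""

    name: str
    f: np.ndarray
    sh3_id: str | None = None
    info: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2 or self.f.shape[1] != len(AA_ALPHABET):
            raise ValueError("PWM must be k x 20")
        self.info = information_vector(self.f)
        if not (self.info > 0).any():
            raise ValueError(f"PWM {self.name}: no informative column")

    @property
    def width(self) -> int:
        return self.f.shape[0]

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[j] for j in self.f.argmax(axis=1))


@dataclass(frozen=True)
class MSSResult:
    sequence_id: str
    pwm_name: str
    max_mss: float
    window_start: int  # 0-based
    window_seq: str


@dataclass(frozen=True)
class NullDistribution:
    kind: str
    samples: np.ndarray
    n: int
    seed: int

    @property
    def threshold_95(self) -> float:
        return float(np.percentile(self.samples, 95))


def _encode(seq: str) -> np.ndarray:
    """Integer-encode a protein sequence; non-standard residues become -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def mss_window(pwm: PWM, window: str) -> float:
    """MSS of a single window whose length equals the PWM width."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    idx = _encode(window)
    if (idx < 0).any():
        raise ValueError(f"non-standard residue in window {window!r}")
    return _window_scores(pwm, idx[None, :])[0]


def _window_scores(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Vectorized MSS for an (n_windows, k) array of residue indices."""
    info = pwm.info
    lo = float((info * pwm.f.min(axis=1)).sum())
    hi = float((info * pwm.f.max(axis=1)).sum())
    if hi <= lo:
        raise ValueError(f"degenerate PWM {pwm.name}: Max == Min")
    weighted = info[:, None] * pwm.f  # k x 20
    current = weighted[np.arange(pwm.width)[None, :], idx].sum(axis=1)
    return (current - lo) / (hi - lo)


def _scan_one(pwm: PWM, idx: np.ndarray) -> tuple[float, int] | None:
    k = pwm.width
    n = len(idx) - k + 1
    if n < 1:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return None
    scores = np.full(n, -np.inf)
    scores[valid] = _window_scores(pwm, windows[valid])
    best = int(np.argmax(scores))  # argmax returns first occurrence: ties go early
    return float(scores[best]), best


def max_mss(pwms: Sequence[PWM] | PWM, sequence: str, sequence_id: str = "") -> MSSResult:
    """Maximum MSS over all windows of a sequence and all PWMs of a domain.

    Windows containing residues outside the 20-letter alphabet are skipped.
    Ties are broken toward the first-scanned window (and first-listed PWM).
    """
    if isinstance(pwms, PWM):
        pwms = [pwms]
    if not pwms:
        raise ValueError("no PWMs supplied")
    idx = _encode(sequence)
    if len(idx) < min(p.width for p in pwms):
        raise ValueError(
            f"sequence length {len(idx)} shorter than every PWM width"
        )
    best: tuple[float, int, PWM] | None = None
    for pwm in pwms:
        hit = _scan_one(pwm, idx)
        if hit is None:
            continue
        score, start = hit
        if best is None or score > best[0]:
            best = (score, start, pwm)
    if best is None:
        raise ValueError("no valid window in sequence for any PWM")
    score, start, pwm = best
    return MSSResult(
        sequence_id=sequence_id,
        pwm_name=pwm.name,
        max_mss=score,
        window_start=start,
        window_seq=sequence[start:start + pwm.width],
    )


def _background_arrays(background: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(background.keys()))
    probs = np.array(list(background.values()), dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("background frequencies must be non-negative and sum to 1")
    return letters, probs / probs.sum()


def random_peptide_null(
    pwms: Sequence[PWM],
    background: Mapping[str, float] | None = None,
    lengths: int | Sequence[int] | Callable[[np.random.Generator], int] | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Max-MSS null from random sequences drawn from a background composition.

    Lengths may be a fixed integer, an empirical pool sampled with
    replacement (e.g., the lengths of the analyzed prey set), or a callable.
    Defaults to a fixed length of 100 residues.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters, probs = _background_arrays(background or YEAST_AA_FREQS)
    min_width = min(p.width for p in pwms)

    def draw_length() -> int:
        if lengths is None:
            return 100
        if isinstance(lengths, int):
            return lengths
        if callable(lengths):
            return int(lengths(rng))
        return int(rng.choice(np.asarray(lengths)))

    samples = np.empty(n)
    for i in range(n):
        L = max(draw_length(), min_width)
        seq = "".join(rng.choice(letters, size=L, p=probs))
        samples[i] = max_mss(pwms, seq).max_mss
    return NullDistribution(kind="random_peptides", samples=samples, n=n, seed=seed)


def pwm_reassignment_test(
    domain_to_preys: Mapping[str, Mapping[str, str]],
    domain_to_pwms: Mapping[str, Sequence[PWM]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shuffle the domain -> PWM assignment and rescore dependent preys.

    `domain_to_preys` maps each domain to its dependent prey sequences
    (id -> sequence). The observed set pools each domain's prey max-MSS
    against its own PWMs; the permuted set pools the same scores after
    randomly re-assigning the PWM sets to domains, repeated until at least
    `n_perm` permuted scores are collected. Returns the observed scores, the
    permuted scores and a two-tailed Mann-Whitney p value.
    """
    domains = [d for d in domain_to_preys if d in domain_to_pwms]
    skipped = set(domain_to_preys) - set(domains)
    if skipped:
        import logging

        logging.getLogger(__name__).info("domains without PWM excluded: %s", sorted(skipped))
    if len(domains) < 2:
        raise ValueError("need at least two domains with PWMs to permute")
    rng = np.random.default_rng(seed)

    def pooled(assignment: Mapping[str, Sequence[PWM]]) -> np.ndarray:
        vals = []
        for d in domains:
            for sid, seq in domain_to_preys[d].items():
                vals.append(max_mss(assignment[d], seq, sid).max_mss)
        return np.asarray(vals)

    observed = pooled(domain_to_pwms)
    permuted: list[np.ndarray] = []
    total = 0
    pwm_sets = [domain_to_pwms[d] for d in domains]
    while total < n_perm:
        order = rng.permutation(len(domains))
        shuffled = {d: pwm_sets[j] for d, j in zip(domains, order)}
        block = pooled(shuffled)
        permuted.append(block)
        total += len(block)
    permuted_all = np.concatenate(permuted)[:n_perm]
    _, p = stats.mannwhitneyu(observed, permuted_all, alternative="two-sided")
    return observed, permuted_all, float(p)


def enrichment_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: str = "greater",
    threshold: float | None = None,
) -> tuple[float, float | None, float | None]:
    """Mann-Whitney rank test of group A scores against group B.

    Returns (p, fraction of A above `threshold`, fraction of B above it);
    the fractions are None when no threshold is given.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be non-empty")
    _, p = stats.mannwhitneyu(a, b, alternative=alternative)
    frac_a = frac_b = None
    if threshold is not None:
        frac_a = float((a >= threshold).mean())
        frac_b = float((b >= threshold).mean())
    return float(p), frac_a, frac_b


def read_pwms(path: str) -> list[PWM]:
    """Read PWMs from a tab-delimited file.

    Format: records introduced by a `>name` line, followed by a header row of
    the 20 one-letter codes and one frequency row per motif position.
    """
    pwms: list[PWM] = []
    name = None
    header: list[str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, header
        if name is not None and rows:
            order = [header.index(a) for a in AA_ALPHABET]
            f = np.asarray(rows, dtype=float)[:, order]
            pwms.append(PWM(name=name, f=f))
        rows, header = [], None

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
            else:
                fields = line.split("\t")
                if header is None:
                    header = [x.strip() for x in fields]
                else:
                    rows.append([float(x) for x in fields])
    flush()
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            fh.write("\t".join(AA_ALPHABET) + "\n")
            for row in pwm.f:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
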